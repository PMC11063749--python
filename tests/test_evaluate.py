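"""Closed-form metric checks, oracle cross-checks against scipy, top-n
semantics and column-ablation importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import narescore as ns
from narescore.evaluate import (DegenerateInputError, evaluate_per_ligand,
                                importance_groups, pcc, r_squared, srcc, topn_success)


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = [1.0, 2.0, 3.0, 6.0]
        assert r_squared(y, [3.0] * 4) == pytest.approx(0.0)

    def test_closed_form_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_actual_undefined(self):
        with pytest.raises(DegenerateInputError):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_can_be_negative(self):
        assert r_squared([1, 2, 3], [3, 2, 1]) < 0


class TestCorrelations:
    def test_pcc_extremes(self):
        x = [0.5, 1.5, 4.0, 9.0]
        assert pcc(x, x) == pytest.approx(1.0)
        assert pcc(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_srcc_reversed_n3_closed_form(self):
        # 1 - 6*(4+0+4)/(3*8) = -1
        assert srcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_srcc_identical_order(self):
        assert srcc([1, 5, 9, 12], [0.1, 0.2, 0.9, 3.0]) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        for fn in (pcc, srcc):
            with pytest.raises(DegenerateInputError):
                fn([1.0, 1.0, 1.0], [1, 2, 3])

    @given(st.integers(0, 10_000))
    def test_pcc_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, s = rng.normal(size=15), rng.normal(size=15)
        assert pcc(x, s) == pytest.approx(stats.pearsonr(x, s).statistic, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_srcc_matches_scipy_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=12).astype(float)  # many ties
        s = rng.normal(size=12)
        assert srcc(x, s) == pytest.approx(stats.spearmanr(x, s).statistic, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_srcc_equals_closed_form_when_tie_free(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        x = rng.permutation(n).astype(float)
        s = rng.permutation(n).astype(float)
        rx, rs = stats.rankdata(x), stats.rankdata(s)
        closed = 1 - 6 * np.sum((rx - rs) ** 2) / (n * (n ** 2 - 1))
        assert srcc(x, s) == pytest.approx(closed, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_invariance_under_monotone_score_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, s = rng.normal(size=10), rng.normal(size=10)
        assert pcc(x, 3.0 * s + 2.0) == pytest.approx(pcc(x, s), abs=1e-12)
        assert srcc(x, np.exp(s)) == pytest.approx(srcc(x, s), abs=1e-12)


class TestTopN:
    def test_best_scored_close_to_native(self):
        assert topn_success([(-5.0, 1.5), (-2.0, 8.0)], n=1)

    def test_no_close_pose_never_succeeds(self):
        poses = [(float(i), 3.0 + i) for i in range(10)]
        assert not any(topn_success(poses, n) for n in (1, 5, 10))

    def test_hit_ranked_fifth_boundary(self):
        poses = [(1.0, 9.0), (2.0, 9.0), (3.0, 9.0), (4.0, 9.0), (5.0, 1.0), (6.0, 0.5)]
        assert not topn_success(poses, 4)
        assert topn_success(poses, 5)

    def test_monotone_in_n(self):
        rng = np.random.default_rng(0)
        poses = list(zip(rng.normal(size=20), rng.uniform(0, 12, size=20)))
        flags = [topn_success(poses, n) for n in range(1, 21)]
        assert flags == sorted(flags)


class TestPerLigand:
    def _table(self):
        # ligand A: score == rmsd (perfect); ligand B: anti-correlated scores
        return pd.DataFrame({
            "ligand_id": ["A"] * 4 + ["B"] * 4,
            "rmsd": [0.5, 2.5, 5.0, 9.0, 1.0, 3.0, 6.0, 11.0],
            "score": [0.5, 2.5, 5.0, 9.0, 4.0, 3.0, 2.0, 1.0],
        })

    def test_hand_checked_two_ligand_table(self):
        report = evaluate_per_ligand(self._table(), n_list=(1, 2))
        by_id = {e.ligand_id: e for e in report.per_ligand}
        assert by_id["A"].pcc == pytest.approx(1.0)
        assert by_id["A"].srcc == pytest.approx(1.0)
        # ligand B hand computation: x=(1,3,6,11), s=(4,3,2,1)
        x, s = np.array([1, 3, 6, 11.0]), np.array([4, 3, 2, 1.0])
        expected = np.sum((x - x.mean()) * (s - s.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((s - s.mean()) ** 2))
        assert by_id["B"].pcc == pytest.approx(expected)
        assert by_id["B"].srcc == pytest.approx(-1.0)
        assert by_id["A"].topn_hits == {1: True, 2: True}
        # ligand B's best-scored pose is its 11 Å decoy; its 1 Å pose is ranked last
        assert by_id["B"].topn_hits == {1: False, 2: False}
        assert report.pcc_mean == pytest.approx((1.0 + expected) / 2)

    def test_reachable_denominator_variant(self):
        table = self._table()
        table.loc[table.ligand_id == "B", "rmsd"] = [3.0, 4.0, 6.0, 11.0]  # no close pose
        report = evaluate_per_ligand(table, n_list=(1,))
        assert report.topn_fraction_all[1] == pytest.approx(0.5)
        assert report.topn_fraction_reachable[1] == pytest.approx(1.0)

    def test_single_scored_pose_rejected(self):
        table = pd.DataFrame({"ligand_id": ["A"], "rmsd": [1.0], "score": [2.0]})
        with pytest.raises(DegenerateInputError):
            evaluate_per_ligand(table)


@pytest.fixture(scope="module")
def trained():
    table = ns.make_planted_table(n_groups=10, rows_per_group=30, seed=3,
                                  n_noise_columns=9)
    plan = ns.systematic_split(table["pdb_id"], k=5)
    scorer = ns.random_search_train(table, plan, n_trials=3, seed=4)
    return table, plan, scorer


class TestImportance:

    def test_informative_column_has_negative_delta_r2(self, trained):
        table, plan, scorer = trained
        entries = ns.delta_r2_importance(scorer, table, plan)
        by_col = {e.column: e for e in entries}
        informative = by_col["G_C.ar|C.ar"]
        assert informative.mean_delta_r2 < 0
        assert len(informative.delta_r2_per_fold) == plan.k

    def test_null_columns_near_zero(self, trained):
        table, plan, scorer = trained
        entries = ns.delta_r2_importance(scorer, table, plan)
        nulls = [e for e in entries if e.column != "G_C.ar|C.ar"]
        assert nulls
        assert max(abs(e.mean_delta_r2) for e in nulls) <= 0.02

    def test_all_zero_column_has_exactly_zero_delta(self, trained):
        table, plan, scorer = trained
        table = table.copy()
        zero_col = "Metal|Metal|inv_r"
        table[zero_col] = 0.0
        plan2 = ns.systematic_split(table["pdb_id"], k=5)
        scorer2 = ns.random_search_train(table, plan2, n_trials=1, seed=5)
        entries = ns.delta_r2_importance(scorer2, table, plan2)
        by_col = {e.column: e for e in entries}
        assert by_col["Metal|Metal"].delta_r2_per_fold == [0.0] * plan2.k

    def test_pair_groups_span_both_kinds(self):
        cols = ["A_N.ar|N.ar|inv_r", "A_N.ar|N.ar|inv_r6", "SCORE.INTER"]
        groups = importance_groups(cols)
        assert groups == {"A_N.ar|N.ar": ["A_N.ar|N.ar|inv_r", "A_N.ar|N.ar|inv_r6"],
                          "SCORE.INTER": ["SCORE.INTER"]}

    def test_unknown_column_rejected(self, trained):
        table, plan, scorer = trained
        with pytest.raises(KeyError):
            ns.delta_r2_importance(scorer, table, plan, columns=["NOPE"])
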