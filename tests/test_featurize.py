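"""Distance-fingerprint computation: closed forms, cutoff semantics, oracle
equivalence, geometric invariances, and column pruning."""

import numpy as np
import pandas as pd
import pytest

import narescore as ns
from narescore.featurize import (FeaturizerConfig, OverlappingAtomsError, apply_mask,
                                 fingerprint, prune_columns)
from narescore.structio import Atom, LigandPose, ReceptorStructure, SchemaError
from conftest import (brute_force_fingerprint, random_rigid_motion,
                      transform_pose, transform_receptor)


def two_atom_system(distance, receptor_resname="A", receptor_atom="P",
                    ligand_element="C"):
    receptor = ReceptorStructure(
        atoms=[Atom(1, receptor_atom, receptor_atom[0], np.zeros(3),
                    residue_name=receptor_resname)],
        source_id="2AT")
    pose = LigandPose(
        atoms=[Atom(1, f"{ligand_element}1", ligand_element,
                    np.array([distance, 0.0, 0.0]), residue_name="LIG"),
               Atom(2, f"{ligand_element}2", ligand_element,
                    np.array([distance + 1.5, 0.0, 0.0]), residue_name="LIG")],
        bonds=[(0, 1, 1.0)], pose_id="p0", ligand_id="L")
    return receptor, pose


class TestClosedForms:
    def test_single_pair_inv_r(self, registry):
        receptor, pose = two_atom_system(2.0)
        config = FeaturizerConfig(cutoff_rc=4.0, kinds=("inv_r",),
                                  include_score_components=False)
        row = fingerprint(receptor, pose, registry, config)
        # receptor P at origin is a backbone atom: N_P.3; ligand C.3 atoms at 2.0 and 3.5
        assert row.values["N_P.3|C.3|inv_r"] == pytest.approx(1 / 2.0 + 1 / 3.5, rel=1e-12)
        other = [v for k, v in row.values.items() if k != "N_P.3|C.3|inv_r"]
        assert all(v == 0.0 for v in other)

    def test_single_pair_inv_r6(self, registry):
        receptor, pose = two_atom_system(2.0)
        config = FeaturizerConfig(cutoff_rc=4.0, kinds=("inv_r6",),
                                  include_score_components=False)
        row = fingerprint(receptor, pose, registry, config)
        assert row.values["N_P.3|C.3|inv_r6"] == pytest.approx(2.0 ** -6 + 3.5 ** -6, rel=1e-12)

    def test_pair_at_exactly_rc_contributes_zero(self, registry):
        # half-open interval [0, Rc): r == Rc is outside
        receptor, pose = two_atom_system(8.0)
        config = FeaturizerConfig(cutoff_rc=8.0, include_score_components=False)
        row = fingerprint(receptor, pose, registry, config)
        assert all(v == 0.0 for v in row.values.values())
        just_inside = FeaturizerConfig(cutoff_rc=8.0 + 1e-9, include_score_components=False)
        row2 = fingerprint(receptor, pose, registry, just_inside)
        assert row2.values["N_P.3|C.3|inv_r"] > 0

    def test_overlapping_atoms_rejected(self, registry):
        receptor, pose = two_atom_system(1e-9)
        with pytest.raises(OverlappingAtomsError):
            fingerprint(receptor, pose, registry, FeaturizerConfig())

    def test_score_components_appended_verbatim(self, registry, toy_complex):
        spec, receptor, reference = toy_complex
        pose, _ = ns.make_pose_ladder(reference, spec)[1]
        row = fingerprint(receptor, pose, registry, FeaturizerConfig())
        for tag, val in pose.score_components.items():
            assert row.values[tag] == val
        no_scores = FeaturizerConfig(include_score_components=False)
        assert "SCORE" not in fingerprint(receptor, pose, registry, no_scores).values


class TestOracleEquivalence:
    @pytest.mark.parametrize("rc", [4.0, 6.0, 8.0, 10.0])
    @pytest.mark.parametrize("template", ["ring", "chain", "metal_complex"])
    def test_matches_brute_force(self, registry, rc, template):
        spec = ns.FixtureSpec(seed=int(rc * 10), ligand_template=template, n_poses=3)
        receptor, reference = ns.make_toy_complex(spec)
        config = FeaturizerConfig(cutoff_rc=rc, kinds=("inv_r", "inv_r6", "inv_r12"),
                                  include_score_components=False)
        for pose, _ in ns.make_pose_ladder(reference, spec, with_scores=False):
            fast = fingerprint(receptor, pose, registry, config).values
            slow = brute_force_fingerprint(receptor, pose, registry, config)
            assert list(fast) == list(slow)
            np.testing.assert_allclose(list(fast.values()), list(slow.values()),
                                       rtol=1e-10, atol=1e-14)


class TestInvariances:
    def test_monotone_in_rc(self, registry, toy_complex):
        spec, receptor, reference = toy_complex
        config = lambda rc: FeaturizerConfig(cutoff_rc=rc, include_score_components=False)
        previous = None
        for rc in range(4, 11):
            values = np.array(list(
                fingerprint(receptor, reference, registry, config(float(rc))).values.values()))
            if previous is not None:
                assert (values >= previous - 1e-15).all()
            previous = values

    def test_rigid_motion_invariance(self, registry, toy_complex):
        spec, receptor, reference = toy_complex
        rng = np.random.default_rng(7)
        base = np.array(list(fingerprint(
            receptor, reference, registry,
            FeaturizerConfig(include_score_components=False)).values.values()))
        for _ in range(3):
            R, t = random_rigid_motion(rng)
            moved = np.array(list(fingerprint(
                transform_receptor(receptor, R, t), transform_pose(reference, R, t),
                registry, FeaturizerConfig(include_score_components=False)).values.values()))
            np.testing.assert_allclose(moved, base, rtol=1e-9, atol=1e-12)

    def test_additivity_over_disjoint_fragments(self, registry, toy_complex):
        spec, receptor, _ = toy_complex
        frag_a = LigandPose(
            atoms=[Atom(1, "C1", "C", receptor.coords.mean(axis=0) + [2, 0, 0]),
                   Atom(2, "O1", "O", receptor.coords.mean(axis=0) + [3.4, 0, 0])],
            bonds=[(0, 1, 1.0)], pose_id="a", ligand_id="A")
        frag_b = LigandPose(
            atoms=[Atom(1, "N1", "N", receptor.coords.mean(axis=0) + [0, 3, 0]),
                   Atom(2, "C1", "C", receptor.coords.mean(axis=0) + [0, 4.4, 0])],
            bonds=[(0, 1, 1.0)], pose_id="b", ligand_id="B")
        union = LigandPose(
            atoms=[Atom(i + 1, a.name, a.element, a.coords.copy())
                   for i, a in enumerate(frag_a.atoms + frag_b.atoms)],
            bonds=[(0, 1, 1.0), (2, 3, 1.0)], pose_id="ab", ligand_id="AB")
        cfg = FeaturizerConfig(include_score_components=False)
        va = fingerprint(receptor, frag_a, registry, cfg).values
        vb = fingerprint(receptor, frag_b, registry, cfg).values
        vu = fingerprint(receptor, union, registry, cfg).values
        np.testing.assert_allclose(
            list(vu.values()), np.array(list(va.values())) + np.array(list(vb.values())),
            rtol=1e-12, atol=1e-15)


class TestPruning:
    def _table(self, registry, toy_complex):
        spec, receptor, reference = toy_complex
        ladder = ns.make_pose_ladder(reference, spec)
        labels = {p.pose_id: d for p, d in ladder}
        return ns.featurize_poses(receptor, [p for p, _ in ladder], registry,
                                  labels=labels)

    def test_zero_columns_dropped_nonzero_retained(self, registry, toy_complex):
        table = self._table(registry, toy_complex)
        pruned, mask = prune_columns(table)
        from narescore.structio import feature_columns
        fp = [c for c in feature_columns(table) if "|" in c]
        zero = [c for c in fp if (table[c] == 0).all()]
        kept_fp = [c for c in mask.retained if "|" in c]
        assert set(kept_fp) == set(fp) - set(zero)
        assert all((table[c] != 0).any() for c in kept_fp)
        # column order preserved
        assert kept_fp == [c for c in fp if c not in set(zero)]

    def test_score_components_never_pruned(self, registry, toy_complex):
        table = self._table(registry, toy_complex)
        table["SCORE.ZERO"] = 0.0
        _, mask = prune_columns(table)
        assert "SCORE.ZERO" in mask.retained

    def test_mask_replay_on_new_rows(self, registry, toy_complex):
        table = self._table(registry, toy_complex)
        pruned, mask = prune_columns(table)
        replayed = apply_mask(table, mask)
        assert list(replayed.columns) == ["pdb_id", "ligand_id", "pose_id", "label"] + mask.retained
        np.testing.assert_array_equal(replayed[mask.retained].to_numpy(),
                                      pruned[mask.retained].to_numpy())

    def test_missing_fingerprint_column_is_schema_error(self, registry, toy_complex):
        table = self._table(registry, toy_complex)
        _, mask = prune_columns(table)
        broken = table.drop(columns=[c for c in mask.retained if "|" in c][:1])
        with pytest.raises(SchemaError):
            apply_mask(broken, mask)

    def test_missing_score_component_zero_filled(self, registry, toy_complex):
        table = self._table(registry, toy_complex)
        _, mask = prune_columns(table)
        assert "SCORE" in mask.retained
        replayed = apply_mask(table.drop(columns=["SCORE"]), mask)
        assert (replayed["SCORE"] == 0).all()


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [dict(cutoff_rc=0.0), dict(cutoff_rc=11.0),
                                     dict(kinds=()), dict(kinds=("inv_r5",))])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            FeaturizerConfig(**bad)
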