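"""Evaluation of pose-scoring performance.

Metrics follow the standard closed forms:

    R^2  = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
    PCC  = sum (x - xbar)(s - sbar) / sqrt(sum (x - xbar)^2 sum (s - sbar)^2)
    SRCC = 1 - 6 sum (R(x) - R(s))^2 / (n (n^2 - 1))        (tie-free)

computed per ligand across its poses (x = actual RMSD, s = score).  With
ties, SRCC generalizes to the Pearson correlation of midrank vectors, which
reduces exactly to the closed form when no ties are present.  Top-n success
asks whether a close-to-native pose (RMSD <= 2 Å) appears among the n
best-scored poses.  Feature importance is measured by column ablation:
zeroing a column group in the validation data and reporting the change in
R^2 per fold (negative change = important feature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .atomtypes import is_fingerprint_column, pair_of_column
from .poselabel import CLOSE_TO_NATIVE_RMSD


class DegenerateInputError(ValueError):
    """A correlation is undefined (constant vector, too few points)."""


def r_squared(actual, predicted) -> float:
    """Coefficient of determination; may be negative for poor predictors."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise DegenerateInputError("need two equal-length vectors of size >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateInputError("R^2 undefined: actual values are constant")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def pcc(x, s) -> float:
    """Pearson correlation between actual RMSD and score."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.shape != s.shape or x.size < 2:
        raise DegenerateInputError("need two equal-length vectors of size >= 2")
    dx, ds = x - x.mean(), s - s.mean()
    denom = np.sqrt(np.sum(dx ** 2) * np.sum(ds ** 2))
    if denom == 0:
        raise DegenerateInputError("PCC undefined: constant input vector")
    return float(np.sum(dx * ds) / denom)


def srcc(x, s) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.shape != s.shape or x.size < 2:
        raise DegenerateInputError("need two equal-length vectors of size >= 2")
    return pcc(rankdata(x), rankdata(s))


def topn_success(scored_poses: list[tuple[float, float]], n: int,
                 threshold: float = CLOSE_TO_NATIVE_RMSD) -> bool:
    """Whether the ``n`` best-scored ``(score, rmsd)`` poses include a
    close-to-native one.  Lower score = better; ties keep input order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    order = np.argsort([s for s, _ in scored_poses], kind="stable")
    return any(scored_poses[i][1] <= threshold for i in order[:n])


@dataclass
class LigandEval:
    """Per-ligand correlation and top-n outcome."""

    ligand_id: str
    n_poses: int
    pcc: float | None
    srcc: float | None
    topn_hits: dict[int, bool]
    has_close_to_native: bool


@dataclass
class EvaluationReport:
    per_ligand: list[LigandEval]
    pcc_mean: float
    pcc_sd: float
    srcc_mean: float
    srcc_sd: float
    #: fraction of ligands with a close-to-native pose in the top n, over all
    #: ligands and over only those able to produce a close-to-native pose
    topn_fraction_all: dict[int, float] = field(default_factory=dict)
    topn_fraction_reachable: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pcc_mean": self.pcc_mean, "pcc_sd": self.pcc_sd,
            "srcc_mean": self.srcc_mean, "srcc_sd": self.srcc_sd,
            "topn_fraction_all": {str(k): v for k, v in self.topn_fraction_all.items()},
            "topn_fraction_reachable": {str(k): v for k, v in self.topn_fraction_reachable.items()},
            "per_ligand": [
                {"ligand_id": e.ligand_id, "n_poses": e.n_poses, "pcc": e.pcc,
                 "srcc": e.srcc, "topn_hits": {str(k): v for k, v in e.topn_hits.items()},
                 "has_close_to_native": e.has_close_to_native}
                for e in self.per_ligand
            ],
        }


def evaluate_per_ligand(table: pd.DataFrame, n_list: tuple[int, ...] = (1, 5, 10),
                        *, rmsd_col: str = "rmsd", score_col: str = "score",
                        ligand_col: str = "ligand_id",
                        threshold: float = CLOSE_TO_NATIVE_RMSD) -> EvaluationReport:
    """Per-ligand PCC/SRCC and top-n close-to-native success.

    Two top-n denominators are reported: all evaluated ligands, and only the
    ligands whose pose set contains at least one close-to-native pose.
    Ligands with a constant score or RMSD vector get no correlation value
    (reported as missing) but still enter the top-n counts.
    """
    evals: list[LigandEval] = []
    for lid, grp in table.groupby(ligand_col, sort=True):
        if len(grp) < 2:
            raise DegenerateInputError(f"ligand {lid}: need >= 2 scored poses")
        x = grp[rmsd_col].to_numpy(dtype=float)
        s = grp[score_col].to_numpy(dtype=float)
        try:
            p = pcc(x, s)
            r = srcc(x, s)
        except DegenerateInputError:
            p = r = None
        pairs = list(zip(s, x))
        hits = {n: topn_success(pairs, n, threshold) for n in n_list}
        evals.append(LigandEval(str(lid), len(grp), p, r, hits,
                                has_close_to_native=bool((x <= threshold).any())))
    pccs = np.array([e.pcc for e in evals if e.pcc is not None])
    srccs = np.array([e.srcc for e in evals if e.srcc is not None])
    reachable = [e for e in evals if e.has_close_to_native]
    top_all, top_reach = {}, {}
    for n in n_list:
        top_all[n] = float(np.mean([e.topn_hits[n] for e in evals])) if evals else np.nan
        top_reach[n] = (float(np.mean([e.topn_hits[n] for e in reachable]))
                        if reachable else np.nan)
    return EvaluationReport(
        per_ligand=evals,
        pcc_mean=float(pccs.mean()) if pccs.size else np.nan,
        pcc_sd=float(pccs.std(ddof=1)) if pccs.size > 1 else np.nan,
        srcc_mean=float(srccs.mean()) if srccs.size else np.nan,
        srcc_sd=float(srccs.std(ddof=1)) if srccs.size > 1 else np.nan,
        topn_fraction_all=top_all,
        topn_fraction_reachable=top_reach,
    )


# ---------------------------------------------------------------------------
# column-ablation feature importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceEntry:
    """Change in validation R^2 when a column group is zeroed (per fold)."""

    column: str
    delta_r2_per_fold: list[float]

    @property
    def mean_delta_r2(self) -> float:
        return float(np.mean(self.delta_r2_per_fold))


def importance_groups(columns: list[str]) -> dict[str, list[str]]:
    """Ablation groups: one group per (receptor, ligand) pair spanning all
    its fingerprint kinds; each score component is its own group."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        key = "|".join(pair_of_column(col)) if is_fingerprint_column(col) else col
        groups.setdefault(key, []).append(col)
    return groups


def delta_r2_importance(scorer, table: pd.DataFrame, plan,
                        columns: list[str] | None = None) -> list[ImportanceEntry]:
    """Column-zeroing importance under the selected hyperparameters.

    For every fold of ``plan``, a model with the scorer's hyperparameter
    draw is fit on the fold's training rows; validation R^2 is computed on
    the original fold data and on a copy with one column group set to zero.
    The entry records ``R^2(zeroed) - R^2(original)`` per fold: negative
    means the feature mattered.
    """
    from .mltrain import fit_fold_models  # deferred: mltrain imports evaluate

    fold_models = fit_fold_models(scorer, table, plan)
    feat_cols = [c for c in scorer.column_mask.retained if c in table.columns]
    groups = importance_groups(feat_cols if columns is None else columns)
    unknown = [c for cols in groups.values() for c in cols if c not in table.columns]
    if unknown:
        raise KeyError(f"unknown columns for importance: {unknown[:5]}")
    entries = []
    for key, cols in groups.items():
        deltas = []
        for model, val_idx, base_r2 in fold_models:
            val = table.loc[val_idx, feat_cols]
            zeroed = val.copy()
            zeroed[cols] = 0.0
            if (val[cols].to_numpy() == 0).all():
                deltas.append(0.0)  # zeroing a zero column is the identity
                continue
            pred = model.predict(zeroed.to_numpy(dtype=float))
            deltas.append(r_squared(table.loc[val_idx, "label"], pred) - base_r2)
        entries.append(ImportanceEntry(column=key, delta_r2_per_fold=deltas))
    return entries
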