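"""Gradient-boosted-tree training of the RMSD predictor.

Data are split by structure identifier (PDB ID) so that no structure
contributes poses to both the training and validation side of any fold:
systematic sampling over the lexicographically sorted IDs assigns the ID at
sorted position p to fold p mod k.  A random hyperparameter search (default
100 draws) trains k fold models per draw with the squared-error objective;
the draw with the highest mean validation R^2 wins and is refit on the full
table.  Everything is deterministic in the input seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost

from .evaluate import r_squared
from .featurize import ColumnMask, FeaturizerConfig, apply_mask
from .structio import SchemaError, feature_columns

logger = logging.getLogger(__name__)

#: hyperparameter search ranges: (low, high, log-scale?, integer?)
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float, bool, bool]] = {
    "n_estimators": (100, 1000, False, True),
    "max_depth": (3, 10, False, True),
    "learning_rate": (0.01, 0.3, True, False),
    "subsample": (0.5, 1.0, False, False),
    "colsample_bytree": (0.5, 1.0, False, False),
    "reg_alpha": (1e-3, 10.0, True, False),
    "reg_lambda": (1e-3, 10.0, True, False),
}

BUNDLE_META = "bundle.json"
BUNDLE_MODEL = "model.json"


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of every PDB ID to one of k folds."""

    fold_of_pdb: dict[str, int]
    k: int

    def fold_indices(self, table: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_row_idx, val_row_idx) per fold, asserting group integrity."""
        folds = table["pdb_id"].map(self.fold_of_pdb)
        if folds.isna().any():
            missing = sorted(table.loc[folds.isna(), "pdb_id"].unique())
            raise KeyError(f"PDB ids not covered by split plan: {missing[:5]}")
        out = []
        for f in range(self.k):
            val = table.index[folds == f].to_numpy()
            train = table.index[folds != f].to_numpy()
            overlap = set(table.loc[val, "pdb_id"]) & set(table.loc[train, "pdb_id"])
            assert not overlap, f"fold {f}: PDB ids leak across the split: {overlap}"
            out.append((train, val))
        return out


@dataclass(frozen=True)
class HyperparameterDraw:
    params: dict[str, float]
    rng_seed: int
    index: int = 0


@dataclass
class TrainedScorer:
    """A trained rescorer: model + the schema needed to featurize new poses
    identically (column mask, featurizer config, registry digest)."""

    model: xgboost.XGBRegressor
    column_mask: ColumnMask
    featurizer_config: FeaturizerConfig
    registry_digest: str
    cv_r2_mean: float
    cv_r2_sd: float
    draw: HyperparameterDraw
    fold_r2: list[float] = field(default_factory=list)


def systematic_split(pdb_ids, k: int = 5) -> SplitPlan:
    """Systematic sampling over sorted PDB IDs: position p -> fold p mod k."""
    ids = sorted(set(map(str, pdb_ids)))
    if len(ids) < k:
        raise ValueError(f"need at least k={k} distinct PDB ids, got {len(ids)}")
    return SplitPlan(fold_of_pdb={pid: p % k for p, pid in enumerate(ids)}, k=k)


def draw_hyperparameters(rng: np.random.Generator, index: int,
                         space: dict = DEFAULT_SEARCH_SPACE) -> HyperparameterDraw:
    params: dict[str, float] = {}
    for name, (lo, hi, log, integer) in space.items():
        if log:
            value = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            value = float(rng.uniform(lo, hi))
        if integer:
            value = int(round(value))
        params[name] = value
    return HyperparameterDraw(params=params, rng_seed=int(rng.integers(2**31 - 1)), index=index)


def _make_model(draw: HyperparameterDraw) -> xgboost.XGBRegressor:
    return xgboost.XGBRegressor(
        objective="reg:squarederror", tree_method="hist",
        random_state=draw.rng_seed, n_jobs=1, verbosity=0, **draw.params)


def _xy(table: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, np.ndarray]:
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite label in training table")
    return X, y


def random_search_train(table: pd.DataFrame, plan: SplitPlan, n_trials: int = 100,
                        seed: int = 0, *, search_space: dict = DEFAULT_SEARCH_SPACE,
                        featurizer_config: FeaturizerConfig | None = None,
                        column_mask: ColumnMask | None = None,
                        registry_digest: str = "") -> TrainedScorer:
    """Cross-validated random hyperparameter search, then refit on all rows.

    For each of ``n_trials`` draws, k fold models are trained and validation
    R^2 is computed per fold; the draw with the highest mean wins (ties ->
    lowest draw index) and its model is refit on the full table.  The refit
    maximizes data use; the per-fold CV statistics of the winning draw are
    kept as the honest generalization estimate.
    """
    cols = feature_columns(table)
    if not cols:
        raise SchemaError("table has no feature columns")
    folds = plan.fold_indices(table)
    for _, val in folds:
        if len(val) < 2:
            raise ValueError("every fold needs >= 2 validation rows")
    rng = np.random.default_rng(seed)
    draws = [draw_hyperparameters(rng, i, search_space) for i in range(n_trials)]
    best: tuple[float, int] | None = None
    best_r2s: list[float] = []
    for draw in draws:
        r2s = []
        for train_idx, val_idx in folds:
            model = _make_model(draw)
            Xt, yt = _xy(table.loc[train_idx], cols)
            Xv, yv = _xy(table.loc[val_idx], cols)
            model.fit(Xt, yt)
            r2s.append(r_squared(yv, model.predict(Xv)))
        mean_r2 = float(np.mean(r2s))
        logger.info("trial %d: mean validation R^2 = %.5f", draw.index, mean_r2)
        if best is None or mean_r2 > best[0]:
            best = (mean_r2, draw.index)
            best_r2s = r2s
    assert best is not None
    winning = draws[best[1]]
    final = _make_model(winning)
    X, y = _xy(table, cols)
    final.fit(X, y)
    return TrainedScorer(
        model=final,
        column_mask=column_mask or ColumnMask(retained=list(cols)),
        featurizer_config=featurizer_config or FeaturizerConfig(),
        registry_digest=registry_digest,
        cv_r2_mean=best[0],
        cv_r2_sd=float(np.std(best_r2s, ddof=1)),
        draw=winning,
        fold_r2=best_r2s,
    )


def fit_fold_models(scorer: TrainedScorer, table: pd.DataFrame, plan: SplitPlan):
    """Refit the winning draw per fold; returns (model, val_idx, val_R^2)
    triples.  Used by the column-ablation importance analysis."""
    cols = [c for c in scorer.column_mask.retained if c in table.columns]
    out = []
    for train_idx, val_idx in plan.fold_indices(table):
        model = _make_model(scorer.draw)
        Xt, yt = _xy(table.loc[train_idx], cols)
        Xv, yv = _xy(table.loc[val_idx], cols)
        model.fit(Xt, yt)
        out.append((model, val_idx, r_squared(yv, model.predict(Xv))))
    return out


def predict_rmsd(scorer: TrainedScorer, rows: pd.DataFrame,
                 registry_digest: str | None = None) -> np.ndarray:
    """Predicted RMSD per row (the docking score; lower = better pose)."""
    if registry_digest is not None and scorer.registry_digest \
            and registry_digest != scorer.registry_digest:
        raise ValueError("registry digest mismatch: poses were featurized with a "
                         "different type registry than the model was trained on")
    masked = apply_mask(rows, scorer.column_mask)
    X = masked[scorer.column_mask.retained].to_numpy(dtype=float)
    pred = scorer.model.predict(X)
    if not np.isfinite(pred).all():
        raise ValueError("non-finite prediction")
    return np.asarray(pred, dtype=float)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

class _BoosterModel:
    """Predict-only wrapper around a raw Booster (used after load)."""

    def __init__(self, booster: xgboost.Booster):
        self.booster = booster

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.booster.predict(xgboost.DMatrix(np.asarray(X, dtype=float)))

    def get_booster(self) -> xgboost.Booster:
        return self.booster


def save_scorer(scorer: TrainedScorer, path) -> None:
    """Persist a scorer as a bundle directory (model + schema + metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scorer.model.get_booster().save_model(path / BUNDLE_MODEL)
    meta = {
        "format": "narescore-bundle-v1",
        "column_mask": scorer.column_mask.retained,
        "featurizer_config": scorer.featurizer_config.to_dict(),
        "registry_digest": scorer.registry_digest,
        "cv_r2_mean": scorer.cv_r2_mean,
        "cv_r2_sd": scorer.cv_r2_sd,
        "fold_r2": scorer.fold_r2,
        "draw": {"params": scorer.draw.params, "rng_seed": scorer.draw.rng_seed,
                 "index": scorer.draw.index},
        "versions": {"xgboost": xgboost.__version__},
    }
    (path / BUNDLE_META).write_text(json.dumps(meta, indent=2))


def load_scorer(path) -> TrainedScorer:
    path = Path(path)
    meta_path = path / BUNDLE_META
    if not meta_path.exists():
        raise FileNotFoundError(f"not a scorer bundle: {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format") != "narescore-bundle-v1":
        raise ValueError(f"unrecognized bundle format in {meta_path}")
    booster = xgboost.Booster()
    booster.load_model(path / BUNDLE_MODEL)
    model = _BoosterModel(booster)
    n_features = booster.num_features()
    if n_features != len(meta["column_mask"]):
        raise ValueError("bundle corrupt: column mask does not match model width")
    draw = HyperparameterDraw(params=meta["draw"]["params"],
                              rng_seed=meta["draw"]["rng_seed"],
                              index=meta["draw"]["index"])
    return TrainedScorer(
        model=model,
        column_mask=ColumnMask(retained=list(meta["column_mask"])),
        featurizer_config=FeaturizerConfig.from_dict(meta["featurizer_config"]),
        registry_digest=meta["registry_digest"],
        cv_r2_mean=meta["cv_r2_mean"],
        cv_r2_sd=meta["cv_r2_sd"],
        draw=draw,
        fold_r2=meta.get("fold_r2", []),
    )
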