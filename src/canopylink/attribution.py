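"""Probabilistic planned/unplanned attribution.

A random-forest classifier maps patch feature vectors to the probability of
an unplanned canopy opening.  Evaluation uses spatial block cross-validation:
patch centroids are binned into a regular hexagonal tessellation (default
cell area 0.5 km^2) and whole hexagons are assigned at random to k folds, so
spatially autocorrelated neighbors never straddle the train/test split.  The
probability cutoff that turns probabilities into the binary classes is
chosen by maximizing the F1-score of the unplanned class on pooled
out-of-fold predictions; 0.39 is shipped as the documented production
default for use without training data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_COLUMNS

log = logging.getLogger(__name__)

#: F1-optimal probability threshold reported for the production European model
DEFAULT_CUTOFF = 0.39


# ---------------------------------------------------------------- hex folds


def hex_circumradius(hex_area_km2: float) -> float:
    """Circumradius (m) of a regular hexagon of the given area: A=(3*sqrt(3)/2)r^2."""
    return float(np.sqrt(hex_area_km2 * 1e6 * 2.0 / (3.0 * np.sqrt(3.0))))


def _axial_hex_ids(x, y, r):
    """Pointy-top axial hex coordinates containing planar points (x, y)."""
    q = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / r
    rr = (2.0 / 3.0 * y) / r
    # cube rounding
    cx, cz = q, rr
    cy = -cx - cz
    rx, ry, rz = np.round(cx), np.round(cy), np.round(cz)
    dx, dy, dz = np.abs(rx - cx), np.abs(ry - cy), np.abs(rz - cz)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx[fix_x] = -ry[fix_x] - rz[fix_x]
    rz[fix_z] = -rx[fix_z] - ry[fix_z]
    return rx.astype(np.int64), rz.astype(np.int64)


@dataclass
class FoldAssignment:
    fold: pd.Series  # patch_id -> fold in 1..k
    hexagon: pd.Series  # patch_id -> hexagon id (int index)
    hex_area_km2: float
    k: int
    seed: int


def make_hex_folds(
    centroids: pd.DataFrame,
    hex_area_km2: float = 0.5,
    k: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Assign patches to spatial folds via a hexagonal tessellation.

    ``centroids`` needs columns centroid_x / centroid_y and a patch_id index.
    Each occupied hexagon is drawn uniformly at random (seeded) into one of
    k folds; every patch inherits the fold of its centroid's hexagon.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if hex_area_km2 <= 0:
        raise ValueError("hex_area_km2 must be > 0")
    r = hex_circumradius(hex_area_km2)
    hq, hr = _axial_hex_ids(
        centroids["centroid_x"].to_numpy(), centroids["centroid_y"].to_numpy(), r
    )
    keys = pd.MultiIndex.from_arrays([hq, hr])
    occupied = sorted(set(keys))
    if len(occupied) < k:
        raise ValueError(
            f"only {len(occupied)} occupied hexagons for {k} folds; "
            "use a smaller hex area or fewer folds"
        )
    rng = np.random.default_rng(seed)
    hex_fold = {h: int(f) for h, f in zip(occupied, rng.integers(1, k + 1, len(occupied)))}
    hex_index = {h: i for i, h in enumerate(occupied)}
    fold = pd.Series([hex_fold[h] for h in keys], index=centroids.index, name="fold")
    hexagon = pd.Series(
        [hex_index[h] for h in keys], index=centroids.index, name="hexagon"
    )
    return FoldAssignment(fold, hexagon, hex_area_km2, k, seed)


# ---------------------------------------------------------------- model


@dataclass
class AttributionModel:
    estimator: RandomForestClassifier
    feature_columns: list[str]
    seed: int
    n_trees: int

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing from input: {missing}")
        X = features[self.feature_columns].to_numpy()
        return self.estimator.predict_proba(X)[:, 1]


def fit_classifier(
    table: pd.DataFrame,
    seed: int,
    n_trees: int = 500,
    feature_columns: list[str] | None = None,
    max_features="sqrt",
) -> AttributionModel:
    """Fit the bagged-tree ensemble on a labeled training table."""
    cols = list(feature_columns or FEATURE_COLUMNS)
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    est.fit(table[cols].to_numpy(), y)
    return AttributionModel(est, cols, int(seed), n_trees)


def rank_auc(labels, scores) -> float:
    """AUC by the rank (Mann-Whitney) statistic, midranks for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def cross_validate(
    table: pd.DataFrame,
    folds: FoldAssignment,
    seed: int,
    n_trees: int = 500,
    feature_columns: list[str] | None = None,
) -> tuple[pd.Series, float]:
    """Spatially blocked out-of-fold probabilities and the pooled rank AUC.

    Each patch's probability comes from a model that never saw its fold.
    A fold holding a single class only triggers a warning; the AUC is still
    computed on the pooled out-of-fold predictions.
    """
    fold = folds.fold.reindex(table.index)
    if fold.isna().any():
        raise ValueError("fold assignment does not cover the training table")
    oof = pd.Series(np.nan, index=table.index, name="p_unplanned")
    for f in sorted(fold.unique()):
        test = fold == f
        train = table[~test]
        if train["label"].nunique() < 2:
            raise ValueError(f"training split for fold {f} is single-class")
        if table.loc[test, "label"].nunique() < 2:
            warnings.warn(f"fold {f} contains a single class only", stacklevel=2)
        model = fit_classifier(
            train, seed=seed, n_trees=n_trees, feature_columns=feature_columns
        )
        oof[test.to_numpy()] = model.predict_proba(table[test])
    return oof, rank_auc(table["label"].to_numpy(), oof.to_numpy())


# ---------------------------------------------------------------- cutoff


@dataclass
class CutoffResult:
    cutoff: float
    f1: float
    accuracy: float


def optimize_cutoff(probs, labels, grid=None) -> CutoffResult:
    """F1-optimal probability cutoff for the unplanned class.

    Evaluates the rule p >= c on the grid {0.01, ..., 0.99} and returns the
    smallest cutoff attaining the maximal F1, with the accuracy achieved.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if grid is None:
        grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    pred = probs[None, :] >= grid[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    fn = ((~pred) & (labels == 1)).sum(axis=1)
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    best = int(np.flatnonzero(f1 == f1.max())[0])
    acc = float((pred[best] == (labels == 1)).mean())
    return CutoffResult(float(grid[best]), float(f1[best]), acc)


# ---------------------------------------------------------------- classify


@dataclass
class AttributionResult:
    table: pd.DataFrame  # patch_id -> p_unplanned, cls
    cutoff: float
    cv_auc: float | None = None
    cv_accuracy: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def classes(self) -> pd.Series:
        return self.table["cls"]


def classify_all(
    model: AttributionModel,
    cutoff: float,
    features: pd.DataFrame,
    cv_auc: float | None = None,
    cv_accuracy: float | None = None,
) -> AttributionResult:
    """Probability and binary class for every patch (labeled or not)."""
    p = model.predict_proba(features)
    cls = np.where(p >= cutoff, "unplanned", "planned")
    out = pd.DataFrame({"p_unplanned": p, "cls": cls}, index=features.index)
    area = features["area_m2"].groupby(out["cls"]).sum() if "area_m2" in features else None
    meta = {
        "n_trees": model.n_trees,
        "seed": model.seed,
        "feature_columns": model.feature_columns,
    }
    if area is not None:
        meta["area_m2_by_class"] = area.to_dict()
    return AttributionResult(out, float(cutoff), cv_auc, cv_accuracy, meta)
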