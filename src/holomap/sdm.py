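"""Random-forest species distribution models with spatial block CV.

The workflow per host species: grid raw occurrence records (one record per
cell, presence wins), add pseudo-absences at cells carrying records of the
other species, split records into 5 spatially blocked folds, fit a 500-tree
classification forest on the nine environmental covariates per fold,
threshold the pooled out-of-fold probabilities at the maximum of
sensitivity+specificity (MSS), and project the fold models onto any
timeframe's layers (mean probability and across-fold SD per cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from holomap.grid import ALL_LAYERS, EnvGridStack

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "SDMResult",
    "add_pseudo_absences",
    "auc",
    "binary_map",
    "confusion_metrics",
    "cross_validate_sdm",
    "fit_rf",
    "grid_records",
    "mss_threshold",
    "project",
    "response_curves",
    "spatial_block_cv",
]


# ---------------------------------------------------------------------------
# record preparation
# ---------------------------------------------------------------------------
def grid_records(records: pd.DataFrame, grid: EnvGridStack) -> pd.DataFrame:
    """Deduplicate records to one per (species, cell); presence wins.

    Records outside the grid extent or on masked cells are dropped (count
    logged).  Coordinates are replaced by cell centroids and a ``cell``
    column (flat index) is added.  Provenance is kept: a cell is 'observed'
    if any of its source records was.
    """
    if records.empty:
        log.warning("grid_records: empty input")
        return records.assign(cell=pd.Series(dtype=int))
    df = records.copy().reset_index(drop=True)
    flat = grid.flat_index(df["lat"].values, df["lon"].values)
    inside = flat >= 0
    ok = inside & grid.mask.ravel()[np.where(inside, flat, 0)]
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("grid_records: dropped %d record(s) outside the masked grid",
                 n_drop)
    df = df.loc[ok].assign(cell=flat[ok])
    out = (df.groupby(["species", "cell"], sort=True)
             .agg(presence=("presence", "max"),
                  source=("source", "min"))  # 'observed' < 'pseudo-absence'
             .reset_index())
    nlon = len(grid.lon)
    i, j = out["cell"] // nlon, out["cell"] % nlon
    out["lat"] = grid.lat[i]
    out["lon"] = grid.lon[j]
    return out[["species", "lat", "lon", "presence", "source", "cell"]]


def add_pseudo_absences(gridded: pd.DataFrame) -> pd.DataFrame:
    """Fill each species' record set with pseudo-absences.

    Every cell holding a record of any *other* species but none of the
    focal species receives an absence flagged ``pseudo-absence``.  After
    augmentation all species share the same record-cell union; observed
    records are never overwritten.
    """
    species = gridded["species"].unique()
    if len(species) < 2:
        log.warning("add_pseudo_absences: single-species dataset, nothing to add")
        return gridded.copy()
    all_cells = gridded[["cell", "lat", "lon"]].drop_duplicates("cell")
    out = []
    for sp in species:
        own = gridded[gridded["species"] == sp]
        missing = all_cells[~all_cells["cell"].isin(own["cell"])]
        pseudo = missing.assign(species=sp, presence=0, source="pseudo-absence")
        out.append(pd.concat([own, pseudo], ignore_index=True))
    return (pd.concat(out, ignore_index=True)
            .sort_values(["species", "cell"]).reset_index(drop=True))


def spatial_block_cv(records: pd.DataFrame, grid: EnvGridStack, k: int = 5,
                     block_size_cells: int = 10) -> np.ndarray:
    """Assign records to ``k`` folds by square spatial blocks.

    Blocks of ``block_size_cells`` x ``block_size_cells`` grid cells are
    assigned greedily (largest record count first, deterministic
    tie-break by block id) to the currently smallest fold, so fold sizes
    are balanced to within one block.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    nlon = len(grid.lon)
    cells = records["cell"].values
    bi = (cells // nlon) // block_size_cells
    bj = (cells % nlon) // block_size_cells
    block = bi * (nlon // block_size_cells + 1) + bj
    uniq, counts = np.unique(block, return_counts=True)
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} occupied spatial blocks for {k} "
                         "folds; shrink block_size_cells")
    order = np.lexsort((uniq, -counts))  # largest first, id breaks ties
    fold_of_block = {}
    fold_sizes = np.zeros(k, dtype=int)
    for b in order:
        f = int(np.argmin(fold_sizes))
        fold_of_block[uniq[b]] = f
        fold_sizes[f] += counts[b]
    return np.array([fold_of_block[b] for b in block], dtype=int)


# ---------------------------------------------------------------------------
# model fitting and metrics
# ---------------------------------------------------------------------------
def fit_rf(X: np.ndarray, y: np.ndarray, n_trees: int = 500,
           seed: int = 0) -> RandomForestClassifier:
    """A classification forest with the conventional defaults (500 trees,
    sqrt(p) candidate features per split, unlimited depth)."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class "
                         "(degenerate CV split)")
    rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def _predict_prob(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    return proba[:, list(model.classes_).index(1)]


def auc(scores, labels) -> float:
    """Rank-based AUC (midranks for ties) — the Mann-Whitney statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    from scipy.stats import rankdata
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def mss_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the midpoints of sorted unique scores plus {0, 1};
    prediction is presence at score >= threshold; ties resolve to the
    smallest maximizing threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("MSS undefined with a single class")
    u = np.unique(s)
    cand = np.concatenate([[0.0], (u[:-1] + u[1:]) / 2.0, [1.0]])
    cand = np.unique(cand)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    pred = s[None, :] >= cand[:, None]
    sens = (pred & (y == 1)).sum(axis=1) / n_pos
    spec = (~pred & (y == 0)).sum(axis=1) / n_neg
    total = sens + spec
    best = total.max()
    return float(cand[np.argmax(total >= best - 1e-12)])


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @classmethod
    def from_predictions(cls, pred, labels) -> "ConfusionMatrix":
        pred = np.asarray(pred, dtype=bool)
        y = np.asarray(labels, dtype=int) == 1
        return cls(tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
                   tn=int((~pred & ~y).sum()), fn=int((~pred & y).sum()))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity and TSS = sensitivity + specificity - 1."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("empty margin: sensitivity/specificity undefined")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    return {"sensitivity": sens, "specificity": spec, "tss": sens + spec - 1.0}


# ---------------------------------------------------------------------------
# cross-validated model set
# ---------------------------------------------------------------------------
@dataclass
class SDMResult:
    """Fold models and CV diagnostics for one species."""

    species: str
    models: list = field(default_factory=list)
    threshold: float = float("nan")
    auc_mean: float = float("nan")
    auc_sd: float = float("nan")
    metrics: dict = field(default_factory=dict)
    importance: dict = field(default_factory=dict)
    oof_scores: np.ndarray | None = None
    oof_labels: np.ndarray | None = None
    folds: np.ndarray | None = None

    def metrics_json(self) -> dict:
        return {"species": self.species, "auc_mean": self.auc_mean,
                "auc_sd": self.auc_sd, "mss": self.threshold,
                **self.metrics, "importance": self.importance}


def cross_validate_sdm(records: pd.DataFrame, grid: EnvGridStack,
                       timeframe: str, k: int = 5, n_trees: int = 500,
                       block_size_cells: int = 10, seed: int = 0) -> SDMResult:
    """Fit the k fold models for one species and derive all CV metrics.

    AUC is computed per fold then summarized as mean +/- SD; the MSS
    threshold is taken on the pooled out-of-fold scores and the fold
    confusion matrices are summed before computing sensitivity/specificity
    and TSS.  Variable importance (Gini impurity decrease) is averaged over
    folds.
    """
    species = records["species"].unique()
    if len(species) != 1:
        raise ValueError("cross_validate_sdm expects a single species")
    X = grid.covariate_matrix(timeframe, cells=records["cell"].values)
    y = records["presence"].values.astype(int)
    folds = spatial_block_cv(records, grid, k=k,
                             block_size_cells=block_size_cells)
    models, aucs = [], []
    oof = np.full(len(y), np.nan)
    cm_total = ConfusionMatrix(0, 0, 0, 0)
    for f in range(k):
        train, test = folds != f, folds == f
        model = fit_rf(X[train], y[train], n_trees=n_trees, seed=seed + f)
        models.append(model)
        scores = _predict_prob(model, X[test])
        oof[test] = scores
        if len(np.unique(y[test])) == 2:
            aucs.append(auc(scores, y[test]))
        else:
            log.warning("fold %d has a single class held out; AUC skipped", f)
    thr = mss_threshold(oof, y)
    for f in range(k):
        test = folds == f
        cm_total = cm_total + ConfusionMatrix.from_predictions(
            oof[test] >= thr, y[test])
    imp = np.mean([m.feature_importances_ for m in models], axis=0)
    return SDMResult(
        species=str(species[0]), models=models, threshold=thr,
        auc_mean=float(np.mean(aucs)), auc_sd=float(np.std(aucs, ddof=1)),
        metrics=confusion_metrics(cm_total),
        importance=dict(zip(ALL_LAYERS, imp.tolist())),
        oof_scores=oof, oof_labels=y, folds=folds,
    )


def project(result: SDMResult, grid: EnvGridStack,
            timeframe: str) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD probability surfaces across the fold models.

    Masked cells stay NaN.  Raises if a covariate layer is missing for the
    requested timeframe.
    """
    for name in ALL_LAYERS:
        if name not in grid.static and name not in grid.dynamic:
            raise KeyError(f"covariate layer {name!r} missing from grid")
    cells = np.flatnonzero(grid.mask.ravel())
    X = grid.covariate_matrix(timeframe, cells=cells)
    preds = np.stack([_predict_prob(m, X) for m in result.models])
    mean = np.full(grid.shape, np.nan).ravel()
    sd = np.full(grid.shape, np.nan).ravel()
    mean[cells] = preds.mean(axis=0)
    sd[cells] = preds.std(axis=0, ddof=0)
    return mean.reshape(grid.shape), sd.reshape(grid.shape)


def binary_map(prob: np.ndarray, threshold: float) -> np.ndarray:
    """Suitable (1) vs unsuitable (0) habitat at ``prob >= threshold``
    (boundary inclusive); NaN cells stay NaN."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out = np.where(prob >= threshold, 1.0, 0.0)
    out[~np.isfinite(prob)] = np.nan
    return out


def response_curves(result: SDMResult, X_train: np.ndarray,
                    covariate: str, n_steps: int = 100
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence response curve for one covariate.

    Sweeps the covariate over its observed range in ``n_steps`` while
    averaging fold-model predictions over the training cells.  A constant
    covariate yields a flat curve (logged).
    """
    idx = ALL_LAYERS.index(covariate)
    lo, hi = np.nanmin(X_train[:, idx]), np.nanmax(X_train[:, idx])
    if lo == hi:
        log.warning("response_curves: covariate %r is constant", covariate)
        grid_vals = np.full(n_steps, lo)
    else:
        grid_vals = np.linspace(lo, hi, n_steps)
    curve = np.empty(n_steps)
    for s, v in enumerate(grid_vals):
        Xs = X_train.copy()
        Xs[:, idx] = v
        curve[s] = float(np.mean([_predict_prob(m, Xs).mean()
                                  for m in result.models]))
    return grid_vals, curve
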