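"""Transfer-accuracy metrics and the reciprocal cross-species matrix.

The central object is the n x n transfer matrix M = (m_ij): the score
(AUC or PPV@k) obtained with species i as the training set and species j
as the testing set, self-prediction included on the diagonal. Column
dispersion summarizes how much the choice of training set matters for a
fixed testing species; the divergence correlation relates transfer
accuracy to the time since two species' most recent common ancestor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DivergenceMatrix, SpeciesDataset
from .nb import NBModel, fit_nb, score_genes

__all__ = [
    "auc",
    "ppv_at_k",
    "tpr_at_prevalence",
    "AUCMatrix",
    "cross_species_matrix",
    "column_dispersion",
    "CorrelationResult",
    "divergence_correlation",
]

log = logging.getLogger(__name__)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied score pairs count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _top_k_order(scores: np.ndarray, gene_ids: Sequence | None, n: int) -> np.ndarray:
    """Indices sorted by descending score, ties by ascending gene_id."""
    ids = np.asarray(gene_ids if gene_ids is not None else np.arange(n))
    return np.lexsort((ids, -scores))


def ppv_at_k(
    scores: Sequence[float],
    labels: Sequence[int],
    k: int = 200,
    gene_ids: Sequence | None = None,
) -> float:
    """Fraction of true essential genes among the top-k scored genes.

    Ties at the k-th score break deterministically: descending score,
    then ascending gene_id (or input position when ids are not given).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if not 1 <= k <= len(scores):
        raise ValueError(f"k must be in [1, {len(scores)}], got {k}")
    order = _top_k_order(scores, gene_ids, len(scores))
    return float(labels[order[:k]].mean())


def tpr_at_prevalence(
    scores: Sequence[float], labels: Sequence[int], gene_ids: Sequence | None = None
) -> float:
    """Recall at the prevalence threshold: of the P positives, the
    fraction recovered in the top-P scored genes (precision = recall
    point). Same tie rule as :func:`ppv_at_k`."""
    labels = _check_binary(labels)
    p = int(labels.sum())
    if p == 0:
        raise ValueError("TPR needs at least one positive")
    scores = np.asarray(scores, dtype=float)
    order = _top_k_order(scores, gene_ids, len(scores))
    return float(labels[order[:p]].sum() / p)


@dataclass
class AUCMatrix:
    """Square transfer matrix: rows train, columns test."""

    species: list[str]
    values: np.ndarray
    metric: str = "auc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and ((finite < 0) | (finite > 1)).any():
            raise ValueError("matrix entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metric: str = "auc") -> "AUCMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column species ids differ")
        return cls(list(frame.index), frame.to_numpy(dtype=float), metric)

    def entry(self, train: str, test: str) -> float:
        return float(self.to_frame().loc[train, test])


def cross_species_matrix(
    datasets: Mapping[str, SpeciesDataset],
    metric: str = "auc",
    k: int = 200,
    *,
    alpha: float = 1.0,
    normalization: str = "rank",
) -> AUCMatrix:
    """Reciprocal transfer matrix over all ordered species pairs.

    Each species' classifier is fitted once and scored against every
    species including itself. A species with single-class labels cannot
    serve as training or testing set; its entries are recorded as NaN
    with a warning rather than failing the whole matrix.
    """
    species = list(datasets)
    if len(species) < 2:
        raise ValueError("need at least two species")
    if metric not in ("auc", "ppv@k"):
        raise ValueError(f"unknown metric {metric!r}")
    models: dict[str, NBModel | None] = {}
    for sp in species:
        try:
            models[sp] = fit_nb(datasets[sp], alpha=alpha, normalization=normalization)
        except ValueError as e:
            warnings.warn(f"species {sp} unusable as training set: {e}")
            models[sp] = None
    n = len(species)
    m = np.full((n, n), np.nan)
    from .nb import normalize_features

    for j, test_sp in enumerate(species):
        test = datasets[test_sp]
        x, y = test.labeled_view()
        if y.sum() in (0, len(y)):
            warnings.warn(f"species {test_sp} has single-class labels; column left missing")
            continue
        x = normalize_features(x, test.schema, normalization)
        for i, train_sp in enumerate(species):
            model = models[train_sp]
            if model is None:
                continue
            s = score_genes(model, x, assume_normalized=True).to_numpy()
            if metric == "auc":
                m[i, j] = auc(s, y)
            else:
                m[i, j] = ppv_at_k(s, y, k=min(k, len(y)), gene_ids=x.index)
    return AUCMatrix(species, m, metric if metric == "auc" else f"ppv@{k}")


def column_dispersion(
    matrix: AUCMatrix, exclude_diagonal: bool = True
) -> pd.DataFrame:
    """Per-testing-species IQR and whisker outliers over training sets.

    Quantiles use linear interpolation; outliers fall outside
    [q1 - 1.5 IQR, q3 + 1.5 IQR]. The diagonal (self-prediction) is
    excluded by default so each column reflects transfer from the other
    species only.
    """
    frame = matrix.to_frame()
    rows = []
    for test_sp in frame.columns:
        col = frame[test_sp]
        if exclude_diagonal:
            col = col.drop(index=test_sp)
        col = col.dropna()
        if len(col) < 4:
            raise ValueError(f"column {test_sp}: need >= 4 training entries, have {len(col)}")
        q1, q3 = np.percentile(col.to_numpy(), [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = sorted(col.index[(col < lo) | (col > hi)])
        rows.append({"species": test_sp, "iqr": iqr, "q1": q1, "q3": q3,
                     "outliers": ",".join(outliers)})
    return pd.DataFrame(rows).set_index("species")


@dataclass
class CorrelationResult:
    """Pearson correlation between transfer accuracy and divergence time."""

    r: float
    p_value: float
    n_used: int
    discarded: list[tuple[str, str]] = field(default_factory=list)
    slope: float = float("nan")
    intercept: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "r": self.r, "p_value": self.p_value, "n_used": self.n_used,
            "discarded": [list(t) for t in self.discarded],
            "slope": self.slope, "intercept": self.intercept,
        }


def _pearson_with_outliers(
    x: np.ndarray, y: np.ndarray, pairs: list[tuple[str, str]], outlier_z: float | None
) -> CorrelationResult:
    keep = np.ones(len(x), dtype=bool)
    if outlier_z is not None and len(x) >= 3:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        sd = resid.std(ddof=0)
        if sd > 0:
            keep = np.abs(resid / sd) <= outlier_z
    if keep.sum() < 3:
        raise ValueError("fewer than 3 pairs remain after outlier removal")
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        r, p = 0.0, 1.0
        slope, intercept = 0.0, float(ys.mean())
    else:
        r, p = stats.pearsonr(xs, ys)
        slope, intercept = np.polyfit(xs, ys, 1)
    discarded = [pairs[i] for i in np.flatnonzero(~keep)]
    return CorrelationResult(float(r), float(p), int(keep.sum()), discarded,
                             float(slope), float(intercept))


def divergence_correlation(
    matrix: AUCMatrix,
    divergence: DivergenceMatrix,
    mode: str = "pooled",
    outlier_z: float | None = 3.0,
) -> CorrelationResult | dict[str, CorrelationResult]:
    """Correlate off-diagonal transfer scores with divergence times.

    ``pooled`` uses every ordered pair (i -> j, i != j); ``per_test``
    returns one result per testing species (one matrix column at a time).
    Outliers by standardized OLS residual beyond ``outlier_z`` are
    discarded before the final fit (None disables removal).
    """
    frame = matrix.to_frame()
    if mode not in ("pooled", "per_test"):
        raise ValueError(f"unknown mode {mode!r}")

    def collect(test_only: str | None):
        xs, ys, pairs = [], [], []
        for train_sp in frame.index:
            for test_sp in frame.columns:
                if train_sp == test_sp:
                    continue
                if test_only is not None and test_sp != test_only:
                    continue
                v = frame.loc[train_sp, test_sp]
                if np.isnan(v):
                    continue
                xs.append(divergence.distance(train_sp, test_sp))
                ys.append(v)
                pairs.append((train_sp, test_sp))
        return np.asarray(xs), np.asarray(ys), pairs

    if mode == "pooled":
        x, y, pairs = collect(None)
        if len(x) < 3:
            raise ValueError("fewer than 3 usable pairs")
        return _pearson_with_outliers(x, y, pairs, outlier_z)
    out = {}
    for test_sp in frame.columns:
        x, y, pairs = collect(test_sp)
        if len(x) < 3:
            log.warning("testing species %s: fewer than 3 pairs, skipped", test_sp)
            continue
        out[test_sp] = _pearson_with_outliers(x, y, pairs, outlier_z)
    return out
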