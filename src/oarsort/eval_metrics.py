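"""Classification and geometric evaluation.

Classification: per-class/macro/weighted precision, recall, F1, plain
accuracy, macro per-label accuracy, confusion matrices (raw and
row-normalized).  Geometric: Dice, HD95 and symmetric mean surface
distance in physical mm, with the superior-truncation rule, plus a
two-sided Wilcoxon signed-rank test (exact by enumeration at small n).

Surface extraction uses 6-connectivity boundary voxels and percentiles
use linear interpolation; both are documented defaults, overridable via
the function arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm

SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    vocabulary: tuple[str, ...]
    precision: np.ndarray          # P_i per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float                # plain accuracy
    macro_label_accuracy: float    # unweighted mean of per-label recall
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    custom_precision: float | None = None
    zero_division_classes: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = {
            c: dict(precision=self.precision[i], recall=self.recall[i],
                    f1=self.f1[i], support=int(self.support[i]))
            for i, c in enumerate(self.vocabulary)
        }
        rows["macro avg"] = dict(precision=self.macro_precision,
                                 recall=self.macro_recall, f1=self.macro_f1,
                                 support=int(self.support.sum()))
        rows["weighted avg"] = dict(precision=self.weighted_precision,
                                    recall=self.weighted_recall,
                                    f1=self.weighted_f1,
                                    support=int(self.support.sum()))
        return pd.DataFrame(rows).T


@dataclass
class ConfusionMatrix:
    vocabulary: tuple[str, ...]
    counts: np.ndarray  # rows = true class, cols = predicted class

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized view; rows with no support stay all-zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=self.vocabulary, columns=self.vocabulary)


def classification_report(
    true_labels, predicted_labels, vocabulary, other_class: str | None = "Other"
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Standard multi-class metrics from two equal-length label lists.

    Zero-division cases (a class never predicted, or never present)
    report 0 and are flagged in ``zero_division_classes``.
    """
    vocabulary = tuple(vocabulary)
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {c: i for i, c in enumerate(vocabulary)}
    for lab in (*true_labels, *predicted_labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in vocabulary")
    n = len(vocabulary)
    counts = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1

    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    support = counts.sum(axis=1)

    flagged = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    for i, c in enumerate(vocabulary):
        if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0:
            flagged.append(c)

    total = max(len(true_labels), 1)
    weighted = lambda x: float((x * support).sum() / support.sum())  # noqa: E731
    cp = None
    if other_class is not None and other_class in index:
        mask = np.arange(n) != index[other_class]
        cp = float(precision[mask].sum())
    report = MetricsReport(
        vocabulary=vocabulary,
        precision=precision, recall=recall, f1=f1, support=support,
        accuracy=float(tp.sum() / total),
        macro_label_accuracy=float(recall.mean()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=weighted(precision),
        weighted_recall=weighted(recall),
        weighted_f1=weighted(f1),
        custom_precision=cp,
        zero_division_classes=tuple(flagged),
    )
    return report, ConfusionMatrix(vocabulary=vocabulary, counts=counts)


# ---------------------------------------------------------------------------
# geometric metrics
# ---------------------------------------------------------------------------

def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError(f"{name} mask is not binary")
    return mask.astype(bool)


@dataclass
class GeometricResult:
    dsc: float
    hd95_mm: float
    msd_mm: float


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks give 1.0 (flagged convention)."""
    a, b = _as_binary(a, "a"), _as_binary(b, "b")
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: in the mask but not in its 6-connected erosion."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=SIX_CONNECTED,
                                    border_value=0)
    return np.argwhere(mask & ~eroded)


def _surface_distances(a: np.ndarray, b: np.ndarray, spacing):
    a, b = _as_binary(a, "a"), _as_binary(b, "b")
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    if not a.any() or not b.any():
        raise ValueError("surface distances are undefined for empty masks")
    spacing = np.asarray(spacing, dtype=float)
    pa = surface_voxels(a) * spacing
    pb = surface_voxels(b) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return d_ab, d_ba


def hd95(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """95th percentile of the pooled symmetric surface-distance set, mm."""
    d_ab, d_ba = _surface_distances(a, b, spacing)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def msd(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Symmetric mean surface distance: mean of the two directed means."""
    d_ab, d_ba = _surface_distances(a, b, spacing)
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def evaluate_masks(pred: np.ndarray, truth: np.ndarray, spacing,
                   truncate: bool = True) -> GeometricResult:
    if truncate:
        pred = truncate_superior(pred, truth)
    return GeometricResult(
        dsc=dice(pred, truth),
        hd95_mm=hd95(pred, truth, spacing),
        msd_mm=msd(pred, truth, spacing),
    )


def truncate_superior(prediction: np.ndarray, ground_truth: np.ndarray) -> np.ndarray:
    """Zero predicted voxels strictly superior to the truth's top slice."""
    prediction = np.asarray(prediction)
    ground_truth = np.asarray(ground_truth)
    if prediction.shape != ground_truth.shape:
        raise ValueError("masks must share one grid")
    nz = np.flatnonzero(ground_truth.any(axis=(1, 2)))
    if nz.size == 0:
        raise ValueError("ground truth mask is empty")
    out = prediction.copy()
    out[int(nz[-1]) + 1:] = 0
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    a, b, exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  The null distribution is enumerated
    exactly (all 2^n sign assignments) for n <= ``exact_max_n``; larger
    n uses the normal approximation with continuity and tie correction.
    Returns (W = min of signed-rank sums, two-sided p).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; no signal to test")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero differences, have {n}")
    ranks = _rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= exact_max_n:
        # enumerate all sign assignments of the observed |d| ranks
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        p_le = np.mean(sums <= w_plus + 1e-12)
        p_ge = np.mean(sums >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity correction toward the mean
    p = min(1.0, 2.0 * norm.cdf(z))
    return w, float(p)


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks with ties (1-based)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
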