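"""Diversity statistics, Bray-Curtis identity calling and ROC calibration.

Identity calling compares the spacer profile of a query sample (typically a
skin or object swab) against a reference profile from the same typing run
(saliva, which is rich in CRISPR spacers). Two samples are called
``same_source`` when their Bray-Curtis dissimilarity is strictly below the
threshold (default 0.8). ROC analysis sweeps that threshold over observed
distances, with same-individual pairs as the positive class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix

from .asv_denoise import ASVTable
from .io_core import SampleMetadata, get_logger

__all__ = [
    "IdentityCall",
    "ROCResult",
    "GroupComparison",
    "SpearmanResult",
    "bray_curtis",
    "observed_otus",
    "shannon",
    "pairwise_distances",
    "call_identity",
    "roc_curve",
    "group_distances",
    "spearman_gated",
    "zscore_standardize",
    "binarize",
    "DEFAULT_IDENTITY_THRESHOLD",
]

log = get_logger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.8


# ---------------------------------------------------------------------------
# Alpha / beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(u,v)) / (sum(u)+sum(v)).

    Inputs are aligned non-negative count vectors. Two all-zero profiles are
    defined as maximally dissimilar (1.0): in heavily diluted samples a
    profile can lose every read, and declaring such pairs identical would be
    a false identity signal.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("count vectors must be non-negative")
    total = u.sum() + v.sum()
    if total == 0:
        log.warning("Bray-Curtis of two empty profiles: defined as 1.0")
        return 1.0
    return float(1.0 - 2.0 * np.minimum(u, v).sum() / total)


def observed_otus(counts: Sequence[float]) -> int:
    """Number of ASVs with strictly positive count (observed richness)."""
    arr = np.asarray(counts, dtype=float)
    return int((arr > 0).sum())


def shannon(counts: Sequence[float], log_base: float = 2.0) -> float:
    """Shannon diversity -sum(p_i * log(p_i)) over nonzero proportions."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def pairwise_distances(table: ASVTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances over the samples of an ASV table."""
    ids = table.sample_ids
    if len(ids) < 2:
        raise ValueError("pairwise distances need at least 2 samples")
    data = table.counts.to_numpy(dtype=float)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = bray_curtis(data[i], data[j])
    return DistanceMatrix(mat, ids=ids)


# ---------------------------------------------------------------------------
# Identity calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentityCall:
    """A thresholded same-source decision for one query/reference pair."""

    query_sample: str
    reference_sample: str
    locus: str
    distance: float
    threshold: float
    call: str  # "same_source" | "different_source"


def call_identity(
    table_or_dm: ASVTable | DistanceMatrix,
    query: str,
    reference: str,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    locus: str = "",
) -> IdentityCall:
    """Call identity by the strict rule distance < threshold -> same_source.

    A distance exactly equal to the threshold is ``different_source``: the
    rule is "below", and false positives are the costly error in forensics.
    """
    if isinstance(table_or_dm, ASVTable):
        ids = table_or_dm.sample_ids
        for s in (query, reference):
            if s not in ids:
                raise KeyError(f"sample {s!r} not in table")
        distance = bray_curtis(
            table_or_dm.sample_counts(query), table_or_dm.sample_counts(reference)
        )
    else:
        distance = float(table_or_dm[query, reference])
    call = "same_source" if distance < threshold else "different_source"
    return IdentityCall(
        query_sample=query,
        reference_sample=reference,
        locus=locus,
        distance=distance,
        threshold=threshold,
        call=call,
    )


# ---------------------------------------------------------------------------
# ROC calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    """Threshold sweep of the classifier "same source iff distance < t"."""

    thresholds: tuple[float, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float
    best_threshold: float
    best_sensitivity: float
    best_specificity: float


def roc_curve(distances: Sequence[float], is_same_individual: Sequence[bool]) -> ROCResult:
    """ROC analysis of distance-based identity calling.

    Positives are same-individual pairs (low distances are "good"). The
    sweep evaluates every distinct observed distance plus boundary points;
    AUC is the trapezoid over (1-specificity, sensitivity), equivalent to
    the pairwise-comparison probability with half credit for ties. The best
    threshold maximizes sensitivity + specificity (Youden); ties prefer the
    higher specificity, then the lower threshold.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(is_same_individual, dtype=bool)
    if d.shape != y.shape:
        raise ValueError("distances and labels must align")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    uniq = np.unique(d)
    eps = 1.0 if uniq.size == 0 else max(1e-9, 1e-9 * abs(uniq[-1]))
    thresholds = np.concatenate(([uniq[0] - eps] if uniq.size else [0.0], uniq, [uniq[-1] + eps]))

    sens = []
    spec = []
    for t in thresholds:
        pred_same = d < t
        tp = int((pred_same & y).sum())
        tn = int((~pred_same & ~y).sum())
        sens.append(tp / n_pos)
        spec.append(tn / n_neg)
    sens_arr = np.array(sens)
    spec_arr = np.array(spec)

    # Trapezoid over the ROC curve; points are already ordered by threshold,
    # hence by increasing FPR and TPR.
    fpr = 1.0 - spec_arr
    auc = float(np.trapezoid(sens_arr, fpr))

    youden = sens_arr + spec_arr
    best_idx = 0
    for i in range(1, len(thresholds)):
        if (youden[i], spec_arr[i], -thresholds[i]) > (
            youden[best_idx], spec_arr[best_idx], -thresholds[best_idx]
        ):
            best_idx = i
    return ROCResult(
        thresholds=tuple(float(t) for t in thresholds),
        sensitivity=tuple(float(s) for s in sens_arr),
        specificity=tuple(float(s) for s in spec_arr),
        auc=auc,
        best_threshold=float(thresholds[best_idx]),
        best_sensitivity=float(sens_arr[best_idx]),
        best_specificity=float(spec_arr[best_idx]),
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Distances partitioned by relatedness, with nonparametric tests."""

    groups: dict[str, list[float]]
    kw_p: float | None
    pairwise_adjusted_p: dict[tuple[str, str], float] = field(default_factory=dict)
    diagnostics: str = ""


GROUP_NAMES = ("within_individual", "within_household", "between_household")


def _pair_group(a: SampleMetadata, b: SampleMetadata) -> str:
    if a.individual == b.individual:
        return "within_individual"
    if a.household and a.household == b.household:
        return "within_household"
    return "between_household"


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact-permutation Mann-Whitney p-value (small groups).

    Enumerates all assignments of the pooled values to the two groups and
    computes the tail probability of |U - n1*n2/2|. Handles ties correctly
    by construction; intended for group sizes <= 8 each.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    observed = _u_statistic(x, y)
    center = n1 * len(y) / 2.0
    dev = abs(observed - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        chosen = set(combo)
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(_u_statistic(gx, gy) - center) >= dev - 1e-12:
            count += 1
    return count / total


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mann_whitney_p(x: Sequence[float], y: Sequence[float], exact_max_n: int = 8) -> float:
    """Two-sided MWU p: exact permutation for small groups, else asymptotic
    (normal approximation with tie correction via scipy)."""
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return mann_whitney_exact(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Multiply-and-cap Bonferroni adjustment."""
    return min(1.0, p * n_comparisons)


def group_distances(
    dm: DistanceMatrix,
    metadata: Iterable[SampleMetadata],
    query_type: str = "skin",
    reference_type: str = "saliva",
) -> GroupComparison:
    """Partition query-vs-reference distances by relatedness and test.

    Query (skin) x reference (saliva) pairs fall into within_individual,
    within_household (different individuals sharing a household) and
    between_household groups. A Kruskal-Wallis test runs across the three
    groups, followed by pairwise Mann-Whitney tests with Bonferroni
    correction (multiplied by the number of comparisons, capped at 1).
    """
    meta = {m.sample_id: m for m in metadata}
    ids = [i for i in dm.ids if i in meta]
    groups: dict[str, list[float]] = {name: [] for name in GROUP_NAMES}
    for qid in ids:
        if meta[qid].sample_type != query_type:
            continue
        for rid in ids:
            if meta[rid].sample_type != reference_type:
                continue
            groups[_pair_group(meta[qid], meta[rid])].append(float(dm[qid, rid]))

    empty = [name for name, vals in groups.items() if not vals]
    if empty:
        return GroupComparison(
            groups=groups,
            kw_p=None,
            diagnostics=f"Kruskal-Wallis skipped: empty group(s) {empty}",
        )

    try:
        with np.errstate(invalid="ignore"):  # all-tie input divides 0/0
            kw_p = float(stats.kruskal(*groups.values()).pvalue)
    except ValueError:
        kw_p = float("nan")
    if math.isnan(kw_p):
        # All pooled values identical: no evidence of any group difference.
        kw_p = 1.0
    pairs = list(itertools.combinations(GROUP_NAMES, 2))
    adjusted = {
        (a, b): bonferroni(mann_whitney_p(groups[a], groups[b]), len(pairs))
        for a, b in pairs
    }
    return GroupComparison(groups=groups, kw_p=kw_p, pairwise_adjusted_p=adjusted)


# ---------------------------------------------------------------------------
# Gated correlation and table transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman correlation with a significance gate.

    The coefficient is always computed (``r`` is None only when undefined,
    e.g. a constant input); ``reported`` says whether it clears the
    significance gate and should be displayed.
    """

    r: float | None
    p_value: float
    reported: bool

    @property
    def suppressed(self) -> bool:
        return not self.reported


def spearman_gated(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> SpearmanResult:
    """Rank correlation (average ranks for ties), reported only if p < alpha.

    A constant input vector makes the coefficient undefined; the result is
    returned suppressed with r = None and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_gated needs paired vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(r=None, p_value=1.0, reported=False)
    res = stats.spearmanr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if math.isnan(r):
        return SpearmanResult(r=None, p_value=1.0, reported=False)
    return SpearmanResult(r=r, p_value=p, reported=bool(p < alpha))


def zscore_standardize(values: Sequence[float]) -> np.ndarray:
    """Z-score with the population (n) denominator; constant rows -> zeros."""
    arr = np.asarray(values, dtype=float)
    sd = arr.std()  # ddof=0
    if sd == 0:
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def binarize(counts: Sequence[float]) -> np.ndarray:
    """Presence/absence transform (count > 0); idempotent."""
    arr = np.asarray(counts, dtype=float)
    return (arr > 0).astype(np.int64)
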