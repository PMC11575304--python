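"""qPCR absolute quantification of CRISPR spacers and the copy-number QC gate.

A standard curve is an ordinary least-squares fit of quantification cycle
(Cq) on log10(copies/uL) over a plasmid dilution series (10^6 down to 10^2
copies/uL). Amplification efficiency follows from the slope as
``(10**(-1/slope) - 1) * 100``; a perfect doubling per cycle gives slope
-log2(10) = -3.3219 and 100% efficiency. Samples quantify below the lowest
standard (the LOQ, 100 copies/uL) are reported but flagged, and the QC gate
requires at least 10^2 spacer copies/uL for a sample to be considered
reliable for typing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_core import DEFAULT_LOQ, CopyTable, get_logger

__all__ = [
    "StandardCurvePoint",
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "copies_from_cq",
    "qc_assess",
    "quantify_sample",
    "summarize_copies",
    "summarize_copies_by_type",
    "efficiency_from_slope",
    "DEFAULT_QC_THRESHOLD",
]

log = get_logger(__name__)

#: Minimal spacer copies/uL proposed for reliable typing results.
DEFAULT_QC_THRESHOLD = 100.0


@dataclass(frozen=True)
class StandardCurvePoint:
    """One calibration point: known copies/uL and its measured Cq."""

    copies_per_ul: float
    cq: float

    def __post_init__(self) -> None:
        if self.copies_per_ul <= 0:
            raise ValueError("standard copies must be positive")
        if self.cq <= 0:
            raise ValueError("Cq must be positive")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted calibration line Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    loq_copies_per_ul: float = DEFAULT_LOQ

    def copies(self, cq: float) -> float:
        """Invert the curve: copies/uL at a given Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one sample x locus with QC flags."""

    sample_id: str
    locus: str
    copies_per_ul: float | None  # None encodes ND (no amplification)
    below_loq: bool
    qc_pass: bool
    advisory: str = ""


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency (%) implied by a standard-curve slope."""
    if slope >= 0:
        raise ValueError("a valid standard curve has negative slope")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(
    points: Sequence[StandardCurvePoint], loq: float | None = None
) -> StandardCurve:
    """OLS fit of Cq on log10(copies) over a dilution series.

    Requires >= 3 points at >= 3 distinct concentrations. ``r_squared`` is
    the squared Pearson correlation of the fit. The LOQ defaults to the
    lowest standard concentration.
    """
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 points")
    copies = np.array([p.copies_per_ul for p in points], dtype=float)
    if len(np.unique(copies)) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    cq = np.array([p.cq for p in points], dtype=float)
    fit = stats.linregress(np.log10(copies), cq)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope >= 0:
        raise ValueError(f"invalid standard curve: non-negative slope {slope:.3f}")
    curve = StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rvalue) ** 2,
        efficiency_pct=efficiency_from_slope(slope),
        loq_copies_per_ul=float(loq) if loq is not None else float(copies.min()),
    )
    log.info(
        "standard curve: slope %.4f, efficiency %.1f%%, r^2 %.4f, LOQ %.0f copies/uL",
        curve.slope, curve.efficiency_pct, curve.r_squared, curve.loq_copies_per_ul,
    )
    return curve


def copies_from_cq(
    cq: float | Sequence[float] | None | Sequence[float | None],
    curve: StandardCurve,
) -> tuple[float | None, bool]:
    """Copies/uL for one sample from one Cq or duplicate Cq values.

    Duplicates are averaged on the copies (linear) scale. A replicate with no
    amplification contributes nothing; if no replicate amplified the result
    is ND (None). Values below the LOQ are still reported, flagged.
    Returns ``(copies_per_ul or None, below_loq)``.
    """
    values = [cq] if cq is None or np.isscalar(cq) else list(cq)
    measured = []
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if v <= 0:
            raise ValueError(f"Cq must be positive, got {v}")
        measured.append(curve.copies(float(v)))
    if not measured:
        return None, True
    copies = float(np.mean(measured))
    return copies, copies < curve.loq_copies_per_ul


def qc_assess(
    copies_per_ul: float | None, threshold: float = DEFAULT_QC_THRESHOLD
) -> tuple[bool, str]:
    """Apply the minimal-copy-number gate (default 10^2 copies/uL).

    ND always fails. Returns ``(qc_pass, advisory text)``.
    """
    if copies_per_ul is None:
        return False, "no amplification (ND): typing results would be unreliable"
    if copies_per_ul >= threshold:
        return True, f"{copies_per_ul:.1f} copies/uL >= {threshold:.0f}: sufficient template"
    return False, (
        f"{copies_per_ul:.1f} copies/uL < {threshold:.0f}: "
        "expect noise-dominated, poorly reproducible spacer profiles"
    )


def quantify_sample(
    sample_id: str,
    locus: str,
    cq_values: Sequence[float | None],
    curve: StandardCurve,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> QuantResult:
    """Full per-sample quantification: invert curve, flag LOQ, apply QC."""
    copies, below = copies_from_cq(cq_values, curve)
    qc_pass, advisory = qc_assess(copies, qc_threshold)
    return QuantResult(
        sample_id=sample_id,
        locus=locus,
        copies_per_ul=copies,
        below_loq=below,
        qc_pass=qc_pass,
        advisory=advisory,
    )


def summarize_copies(
    copy_table: CopyTable,
    sample_ids: Iterable[str],
    locus: str,
) -> float:
    """Arithmetic mean copies/uL over the selected sample x locus rows.

    ND rows contribute 0 with the row still counted in the denominator;
    below-LOQ values are included as reported. Raises on an empty selection.
    """
    rows = copy_table.select(sample_ids=list(sample_ids), locus=locus)
    if not rows:
        raise ValueError(f"no copy-table rows for locus {locus!r}")
    return float(np.mean([r.numeric_copies() for r in rows]))


def summarize_copies_by_type(
    copy_table: CopyTable,
    metadata,
    sample_type: str,
    locus: str,
) -> float:
    """Mean copies/uL over all samples of one type (skin/saliva/object)."""
    ids = [m.sample_id for m in metadata if m.sample_type == sample_type]
    return summarize_copies(copy_table, ids, locus)
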