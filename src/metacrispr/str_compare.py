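"""Compare called STR genotype profiles against reference profiles.

Capillary-electrophoresis STR typing of low-biomass samples loses alleles
(dropout) and gains artifact peaks such as stutter (drop-in). This module
consumes genotype tables (locus -> allele set) called upstream and scores
them against single-source reference profiles: a locus is *correct* only
when the called allele set equals the reference set exactly. Profile-level
results are summarized as correct-locus counts and percentages over the
21-locus autosomal panel, the complementation metric used when weighing
microbiome typing against human DNA typing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_core import get_logger

__all__ = [
    "GLOBALFILER_AUTOSOMAL_PANEL",
    "STRProfile",
    "LocusComparison",
    "ProfileComparison",
    "compare_locus",
    "compare_profile",
    "summarize_profiles",
    "read_profiles",
    "write_profiles",
    "round_half_up",
]

log = get_logger(__name__)

#: The 21 autosomal loci of the GlobalFiler panel (the three non-autosomal
#: markers of the kit are excluded from profile scoring).
GLOBALFILER_AUTOSOMAL_PANEL: tuple[str, ...] = (
    "D3S1358", "vWA", "D16S539", "CSF1PO", "TPOX", "D8S1179", "D21S11",
    "D18S51", "D2S441", "D19S433", "TH01", "FGA", "D22S1045", "D5S818",
    "D13S317", "D7S820", "SE33", "D10S1248", "D1S1656", "D12S391", "D2S1338",
)

MAX_ALLELES_PER_LOCUS = 4


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (57.5 -> 58)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class STRProfile:
    """Genotype of one sample over an ordered locus panel.

    An empty allele set at a locus means no call. Homozygotes are encoded as
    single-allele sets (not doubled).
    """

    sample_id: str
    genotype: Mapping[str, frozenset[str]]
    panel: tuple[str, ...] = GLOBALFILER_AUTOSOMAL_PANEL

    def __post_init__(self) -> None:
        genotype = {locus: frozenset(alleles) for locus, alleles in self.genotype.items()}
        for locus in self.panel:
            genotype.setdefault(locus, frozenset())
        extra = set(genotype) - set(self.panel)
        if extra:
            raise ValueError(f"{self.sample_id}: loci outside panel: {sorted(extra)}")
        for locus, alleles in genotype.items():
            if len(alleles) > MAX_ALLELES_PER_LOCUS:
                log.warning(
                    "%s/%s: %d alleles called (possible mixture)",
                    self.sample_id, locus, len(alleles),
                )
        object.__setattr__(self, "genotype", genotype)

    def alleles(self, locus: str) -> frozenset[str]:
        return self.genotype[locus]


LOCUS_STATUSES = ("correct", "dropout_only", "dropin_only", "dropout_and_dropin", "no_call")


@dataclass(frozen=True)
class LocusComparison:
    """Per-locus error category of a called vs reference allele set."""

    locus: str
    status: str
    called: frozenset[str]
    reference: frozenset[str]


def compare_locus(locus: str, called: Iterable[str], reference: Iterable[str]) -> LocusComparison:
    """Classify one locus: exact set equality is correct, else an error class.

    - no alleles called -> ``no_call``
    - proper subset of the reference -> ``dropout_only``
    - proper superset -> ``dropin_only`` (includes a heterozygote called over
      a homozygous reference sharing the allele)
    - anything else -> ``dropout_and_dropin``
    """
    called = frozenset(str(a) for a in called)
    reference = frozenset(str(a) for a in reference)
    if not reference:
        raise ValueError(f"{locus}: reference genotype must be non-empty")
    if called == reference:
        status = "correct"
    elif not called:
        status = "no_call"
    elif called < reference:
        status = "dropout_only"
    elif called > reference:
        status = "dropin_only"
    else:
        status = "dropout_and_dropin"
    return LocusComparison(locus=locus, status=status, called=called, reference=reference)


@dataclass(frozen=True)
class ProfileComparison:
    """Profile-level score: correct loci out of the panel total."""

    sample_id: str
    correct_loci: int
    total_loci: int
    per_locus: tuple[LocusComparison, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.correct_loci <= self.total_loci:
            raise ValueError("correct loci count out of range")

    @property
    def rate_pct(self) -> int:
        """Correct-locus rate as a half-up-rounded integer percentage."""
        return round_half_up(100.0 * self.correct_loci / self.total_loci)

    @property
    def full_profile(self) -> bool:
        return self.correct_loci == self.total_loci

    @classmethod
    def from_counts(cls, sample_id: str, correct: int, total: int = 21) -> "ProfileComparison":
        """Build a comparison from a printed correct-locus count."""
        return cls(sample_id=sample_id, correct_loci=correct, total_loci=total)


def compare_profile(called: STRProfile, reference: STRProfile) -> ProfileComparison:
    """Score a called profile against its reference over a shared panel."""
    if called.panel != reference.panel:
        raise ValueError("called and reference profiles use different panels")
    per_locus = tuple(
        compare_locus(locus, called.alleles(locus), reference.alleles(locus))
        for locus in called.panel
    )
    correct = sum(1 for lc in per_locus if lc.status == "correct")
    return ProfileComparison(
        sample_id=called.sample_id,
        correct_loci=correct,
        total_loci=len(called.panel),
        per_locus=per_locus,
    )


def summarize_profiles(comparisons: Sequence[ProfileComparison]) -> tuple[int, int]:
    """(full-profile count, mean correct-locus rate % rounded half-up)."""
    if not comparisons:
        raise ValueError("summarize_profiles needs at least one comparison")
    full = sum(1 for c in comparisons if c.full_profile)
    mean_rate = sum(c.rate_pct for c in comparisons) / len(comparisons)
    return full, round_half_up(mean_rate)


# ---------------------------------------------------------------------------
# Profile TSV I/O (sample_id, locus, comma-separated alleles)
# ---------------------------------------------------------------------------


def read_profiles(
    path: str | Path, panel: tuple[str, ...] = GLOBALFILER_AUTOSOMAL_PANEL
) -> dict[str, STRProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "locus", "alleles"}
    if missing := required - set(df.columns):
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    genotypes: dict[str, dict[str, frozenset[str]]] = {}
    for _, row in df.iterrows():
        alleles = frozenset(a.strip() for a in row["alleles"].split(",") if a.strip())
        genotypes.setdefault(row["sample_id"], {})[row["locus"]] = alleles
    return {
        sid: STRProfile(sample_id=sid, genotype=geno, panel=panel)
        for sid, geno in genotypes.items()
    }


def write_profiles(profiles: Iterable[STRProfile], path: str | Path) -> None:
    rows = []
    for profile in profiles:
        for locus in profile.panel:
            rows.append(
                {
                    "sample_id": profile.sample_id,
                    "locus": locus,
                    "alleles": ",".join(sorted(profile.alleles(locus))),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
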