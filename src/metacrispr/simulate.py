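"""Generative model for synthetic CRISPR spacer amplicon experiments.

The simulator emulates the physics that make low-biomass spacer typing
fragile:

* **Template sampling** — the number of template molecules pipetted into a
  reaction is Poisson(copies/uL x volume), so at 10^0-10^1 copies the
  reaction may contain zero or one template.
* **PCR dispersion** — each template x spacer amplification unit receives a
  lognormal amplification factor (sigma = 0.6), so profiles built from few
  templates are skewed.
* **Competition with primer dimers** — spacer amplicons share the sequencer
  with a background of primer-dimer product. Signal reads are drawn
  Binomial(read_depth, M_s / (M_s + background_mass)) where M_s is the total
  amplified spacer mass; with the default background mass of 100 units the
  signal yield collapses in the 10^1-10^2 spacer-copy window, which is where
  replicate reproducibility is empirically lost. Dimer reads themselves are
  Poisson(dimer_reads_expected) and dominate no-template controls.
* **Noise** — per-base substitution errors (PCR errors fixed in the
  molecule, hence shared by both mates) and a global pool of contaminant
  spacer amplicons at a small rate.

Individuals are modelled as spacer pools: a saliva repertoire with Dirichlet
frequencies, of which the skin carries a subset; cohabiting individuals
share a fixed fraction of their spacer support with household-specific
spacers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .asv_denoise import ASVTable, collapse_errors, dereplicate, drop_empty
from .diversity_identity import bray_curtis
from .io_core import (
    PRIMER_SETS,
    PrimerSet,
    Read,
    ReadPair,
    derive_seed,
    get_logger,
    revcomp,
)
from .spacer_extract import ExtractParams, classify_artifact, _trim_readthrough
from .spacer_extract import ArtifactLabel, extract_sample

__all__ = [
    "SimConfig",
    "SimCRISPRArray",
    "IndividualPool",
    "DIMER_INSERTS",
    "make_array",
    "make_household",
    "make_households",
    "make_contaminant_pool",
    "simulate_sample",
    "simulate_cq",
    "dilution_experiment",
]

log = get_logger(__name__)

#: Post-trim insert sequences left by primer dimers, per locus: the CRISPR3
#: artifact is the reverse complement of the 5' end of the reverse-primer
#: Illumina tail; the CRISPR1 artifact is a fragment of the forward fusion
#: primer.
DIMER_INSERTS: dict[str, str] = {
    "CRISPR3": "ACATCTCCGAGCCCACGAGAC",
    "CRISPR1": "ACTCTCAAGATTTAAGTAACT",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated amplicon sequencing run."""

    seed: int = 0
    read_depth: int = 20_000  # sequencer output budget for spacer signal
    template_volume_ul: float = 1.0  # template volume pipetted per reaction
    per_base_error_rate: float = 0.001
    dimer_reads_expected: float = 15_000.0  # Poisson mean of dimer reads
    contaminant_rate: float = 0.001  # contaminant fraction of read depth
    household_shared_fraction: float = 0.3
    pcr_dispersion_sigma: float = 0.6
    background_mass: float = 100.0  # dimer/background competition, mass units
    saliva_richness: int = 60  # distinct spacers per individual saliva pool
    skin_subsample_fraction: float = 0.6  # share of saliva support on skin
    base_quality: int = 35
    error_quality: int = 20

    def __post_init__(self) -> None:
        for name in ("per_base_error_rate", "contaminant_rate", "household_shared_fraction", "skin_subsample_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "SimConfig":
        return cls(**dict(mapping))


@dataclass(frozen=True)
class SimCRISPRArray:
    """A cloned standard CRISPR array: ordered distinct spacers of one locus."""

    locus_name: str
    primers: PrimerSet
    spacers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.spacers)) != len(self.spacers):
            raise ValueError("array spacers must be pairwise distinct")

    def amplicons(self) -> list[str]:
        return [make_amplicon(self.primers, s) for s in self.spacers]


@dataclass(frozen=True)
class IndividualPool:
    """Per-individual spacer repertoire with household sharing."""

    individual_id: str
    household_id: str
    spacer_frequencies: Mapping[str, float]  # saliva pool, sums to 1
    skin_spacers: tuple[str, ...]  # support subset present on skin
    saliva_richness: int
    skin_subsample_fraction: float
    locus_name: str = "CRISPR3"

    def __post_init__(self) -> None:
        total = sum(self.spacer_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool frequencies sum to {total}, not 1")
        if not set(self.skin_spacers) <= set(self.spacer_frequencies):
            raise ValueError("skin pool support must be a subset of the saliva pool")

    def frequencies(self, source: str) -> dict[str, float]:
        """Spacer frequencies for a sample source ('saliva' or 'skin')."""
        if source == "saliva":
            return dict(self.spacer_frequencies)
        if source in ("skin", "object"):
            sub = {s: self.spacer_frequencies[s] for s in self.skin_spacers}
            total = sum(sub.values())
            return {s: f / total for s, f in sub.items()}
        raise ValueError(f"unknown sample source {source!r}")


def make_amplicon(primers: PrimerSet, insert: str) -> str:
    """Amplicon layout: forward locus primer + insert + revcomp(reverse)."""
    return primers.fwd_locus + insert + revcomp(primers.rev_locus)


# ---------------------------------------------------------------------------
# Spacer / pool construction
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_spacer(
    rng: np.random.Generator,
    primers: PrimerSet,
    len_range: tuple[int, int],
    taken: set[str],
) -> str:
    """Rejection-sample a spacer that survives extraction exactly.

    Rejects candidates that collide with an existing spacer, classify as a
    primer-dimer artifact, or contain a spurious read-through match into the
    opposite primer (which would truncate the recovered insert).
    """
    lo, hi = len_range
    if not (1 <= lo <= hi):
        raise ValueError(f"infeasible spacer length range {len_range}")
    for _ in range(10_000):
        length = int(rng.integers(lo, hi + 1))
        spacer = "".join(rng.choice(_BASES, size=length))
        if spacer in taken:
            continue
        if classify_artifact(spacer, primers) is not ArtifactLabel.OK:
            continue
        if _trim_readthrough(spacer + revcomp(primers.rev_locus), revcomp(primers.rev_locus)) != spacer:
            continue
        rc = revcomp(spacer)
        if _trim_readthrough(rc + revcomp(primers.fwd_locus), revcomp(primers.fwd_locus)) != rc:
            continue
        return spacer
    raise RuntimeError("could not sample a valid spacer (constraints too tight)")


def make_array(
    locus: str | PrimerSet,
    n_spacers: int,
    spacer_len_range: tuple[int, int] = (20, 40),
    seed: int = 0,
) -> SimCRISPRArray:
    """Build a standard CRISPR array of ``n_spacers`` distinct random spacers."""
    if n_spacers < 1:
        raise ValueError("an array needs at least one spacer")
    primers = PRIMER_SETS[locus] if isinstance(locus, str) else locus
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    spacers = []
    for _ in range(n_spacers):
        spacer = _random_spacer(rng, primers, spacer_len_range, taken)
        taken.add(spacer)
        spacers.append(spacer)
    return SimCRISPRArray(locus_name=primers.locus_name, primers=primers, spacers=tuple(spacers))


def make_household(
    household_id: str,
    individual_ids: Sequence[str],
    primers: PrimerSet,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    spacer_len_range: tuple[int, int] = (20, 40),
) -> list[IndividualPool]:
    """Build cohabiting individuals sharing a fraction of spacer support.

    ``round(household_shared_fraction * saliva_richness)`` spacers are common
    to every member; the remainder of each member's repertoire is private.
    Frequencies are Dirichlet(1) per individual (support is shared within a
    household, abundances are not).
    """
    if not individual_ids:
        raise ValueError("a household needs at least one individual")
    rng = np.random.default_rng(derive_seed(seed, "household", household_id))
    richness = config.saliva_richness
    n_shared = int(round(config.household_shared_fraction * richness))
    taken: set[str] = set()
    shared = [_take_spacer(rng, primers, spacer_len_range, taken) for _ in range(n_shared)]
    pools = []
    for ind in individual_ids:
        private = [
            _take_spacer(rng, primers, spacer_len_range, taken)
            for _ in range(richness - n_shared)
        ]
        support = shared + private
        freqs = rng.dirichlet(np.ones(len(support)))
        n_skin = max(1, int(round(config.skin_subsample_fraction * richness)))
        skin_idx = rng.choice(len(support), size=n_skin, replace=False)
        pools.append(
            IndividualPool(
                individual_id=ind,
                household_id=household_id,
                spacer_frequencies=dict(zip(support, freqs.tolist())),
                skin_spacers=tuple(support[i] for i in sorted(skin_idx)),
                saliva_richness=richness,
                skin_subsample_fraction=config.skin_subsample_fraction,
                locus_name=primers.locus_name,
            )
        )
    return pools


def _take_spacer(rng, primers, len_range, taken: set[str]) -> str:
    spacer = _random_spacer(rng, primers, len_range, taken)
    taken.add(spacer)
    return spacer


def make_households(
    layout: Mapping[str, Sequence[str]],
    primers: PrimerSet,
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> list[IndividualPool]:
    """Build several households; supports are disjoint across households."""
    pools: list[IndividualPool] = []
    for household_id, individuals in layout.items():
        pools.extend(
            make_household(household_id, individuals, primers, config, seed=seed)
        )
    return pools


def make_contaminant_pool(
    primers: PrimerSet,
    size: int = 20,
    seed: int = 0,
    spacer_len_range: tuple[int, int] = (20, 40),
) -> tuple[str, ...]:
    """Global pool of environmental contaminant spacers for one locus."""
    rng = np.random.default_rng(derive_seed(seed, "contaminants", primers.locus_name))
    taken: set[str] = set()
    return tuple(_take_spacer(rng, primers, spacer_len_range, taken) for _ in range(size))


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def simulate_sample(
    source: SimCRISPRArray | IndividualPool,
    config: SimConfig,
    copies_per_ul: float,
    seed: int = 0,
    sample_id: str = "sim",
    source_type: str = "saliva",
    contaminants: Sequence[str] = (),
) -> list[ReadPair]:
    """Simulate one sequencing library as a list of read pairs.

    ``source`` is either a cloned standard array (every template molecule
    carries all spacers of the array) or an individual's pool (each template
    is a genome fragment carrying one spacer drawn from the pool
    frequencies). ``copies_per_ul = 0`` simulates a no-template control.
    Deterministic: same seed + config + inputs give byte-identical output.
    """
    if copies_per_ul < 0:
        raise ValueError("copies_per_ul must be non-negative")
    rng = np.random.default_rng(seed)
    if isinstance(source, SimCRISPRArray):
        primers = source.primers
        spacers = list(source.spacers)
        freqs = None  # a plasmid template carries the whole array
    else:
        primers = PRIMER_SETS[source.locus_name]
        freq_map = source.frequencies(source_type)
        spacers = sorted(freq_map)
        freqs = np.array([freq_map[s] for s in spacers])
        freqs = freqs / freqs.sum()

    n_templates = int(rng.poisson(copies_per_ul * config.template_volume_ul))

    # Amplification units: template x spacer for arrays; one spacer draw per
    # template for pools. Each unit gets a lognormal amplification factor.
    if n_templates == 0:
        unit_spacer_idx = np.zeros(0, dtype=np.int64)
    elif freqs is None:
        unit_spacer_idx = np.tile(np.arange(len(spacers)), n_templates)
    else:
        unit_spacer_idx = rng.choice(len(spacers), size=n_templates, p=freqs)
    masses = rng.lognormal(0.0, config.pcr_dispersion_sigma, size=unit_spacer_idx.size)

    signal_mass = float(masses.sum())
    p_signal = signal_mass / (signal_mass + config.background_mass) if signal_mass > 0 else 0.0
    depth_signal = int(rng.binomial(config.read_depth, p_signal)) if p_signal > 0 else 0

    reads_per_spacer = np.zeros(len(spacers), dtype=np.int64)
    if depth_signal > 0:
        unit_reads = rng.multinomial(depth_signal, masses / signal_mass)
        np.add.at(reads_per_spacer, unit_spacer_idx, unit_reads)

    n_dimers = int(rng.poisson(config.dimer_reads_expected))
    n_contam = int(rng.poisson(config.read_depth * config.contaminant_rate)) if contaminants else 0

    pairs: list[ReadPair] = []
    counter = 0
    for idx, n_reads in enumerate(reads_per_spacer):
        if n_reads:
            counter = _emit_reads(
                pairs, make_amplicon(primers, spacers[idx]), int(n_reads),
                rng, config, sample_id, counter,
            )
    if n_dimers:
        dimer_amplicon = make_amplicon(primers, DIMER_INSERTS[primers.locus_name])
        counter = _emit_reads(pairs, dimer_amplicon, n_dimers, rng, config, sample_id, counter)
    if n_contam:
        picks = rng.integers(0, len(contaminants), size=n_contam)
        for i in picks:
            counter = _emit_reads(
                pairs, make_amplicon(primers, contaminants[int(i)]), 1,
                rng, config, sample_id, counter,
            )
    log.info(
        "%s: %.0f copies/uL -> %d templates, %d signal + %d dimer + %d contaminant reads",
        sample_id, copies_per_ul, n_templates, int(reads_per_spacer.sum()), n_dimers, n_contam,
    )
    return pairs


def _emit_reads(
    pairs: list[ReadPair],
    amplicon: str,
    n_reads: int,
    rng: np.random.Generator,
    config: SimConfig,
    sample_id: str,
    counter: int,
) -> int:
    """Append ``n_reads`` read pairs of one amplicon, with shared PCR errors."""
    length = len(amplicon)
    base_qual = (config.base_quality,) * length
    n_errors = rng.binomial(length, config.per_base_error_rate, size=n_reads)
    clean = int((n_errors == 0).sum())

    # Error-free reads are identical; emit them with one shared template.
    r1_seq = amplicon
    r2_seq = revcomp(amplicon)
    for _ in range(clean):
        rid = f"{sample_id}:{counter}"
        pairs.append(
            ReadPair(Read(rid, r1_seq, base_qual), Read(rid, r2_seq, base_qual))
        )
        counter += 1

    for k in n_errors[n_errors > 0]:
        seq = list(amplicon)
        qual = list(base_qual)
        positions = rng.choice(length, size=int(k), replace=False)
        for pos in positions:
            current = seq[pos]
            options = [b for b in "ACGT" if b != current]
            seq[pos] = options[int(rng.integers(0, 3))]
            qual[pos] = config.error_quality
        mutated = "".join(seq)
        qual_t = tuple(qual)
        rid = f"{sample_id}:{counter}"
        pairs.append(
            ReadPair(
                Read(rid, mutated, qual_t),
                Read(rid, revcomp(mutated), qual_t[::-1]),
            )
        )
        counter += 1
    return counter


def simulate_cq(
    copies_per_ul: float,
    slope: float = -3.321928,
    intercept: float = 38.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Ideal-curve Cq for a copy number, with optional Gaussian noise."""
    if copies_per_ul <= 0:
        raise ValueError("copies must be positive to produce a Cq")
    cq = slope * np.log10(copies_per_ul) + intercept
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an explicit rng")
        cq += rng.normal(0.0, noise_sd)
    return float(cq)


# ---------------------------------------------------------------------------
# Dilution experiment (reproducibility vs copy number)
# ---------------------------------------------------------------------------


def dilution_experiment(
    array: SimCRISPRArray,
    config: SimConfig = SimConfig(),
    copies_list: Sequence[float] = (1000.0, 100.0, 10.0, 1.0),
    replicates: int = 3,
    seed: int = 0,
    params: ExtractParams = ExtractParams(),
) -> tuple[ASVTable, pd.DataFrame]:
    """Serial-dilution reproducibility experiment on a standard array.

    Simulates ``replicates`` libraries at each copy number, runs extraction
    and denoising, and computes the Bray-Curtis distance of every replicate
    against a reference profile (the first replicate at the highest copy
    number). Returns the denoised ASV table and a tidy copies-vs-distance
    summary.
    """
    contaminants = make_contaminant_pool(array.primers, seed=derive_seed(seed, "pool"))
    per_sample: dict[str, dict[str, int]] = {}
    rows = []
    for copies in copies_list:
        for rep in range(replicates):
            sid = f"{array.locus_name}_c{copies:g}_r{rep}"
            pairs = simulate_sample(
                array, config, copies,
                seed=derive_seed(seed, array.locus_name, copies, rep),
                sample_id=sid, contaminants=contaminants,
            )
            observations, _ = extract_sample(
                (p.r1 for p in pairs), (p.r2 for p in pairs),
                array.primers, params, sample_id=sid,
            )
            per_sample[sid] = {o.seq: o.count for o in observations}
            rows.append({"sample_id": sid, "copies_per_ul": copies, "replicate": rep})

    table = ASVTable.from_counts(per_sample)
    table = drop_empty(collapse_errors(table))

    reference_id = f"{array.locus_name}_c{max(copies_list):g}_r0"
    ref_counts = table.sample_counts(reference_id)
    summary = pd.DataFrame(rows)
    summary["bray_curtis_to_reference"] = [
        bray_curtis(table.sample_counts(row["sample_id"]), ref_counts)
        for _, row in summary.iterrows()
    ]
    return table, summary
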