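"""Shared domain types, file formats, configuration and seeded randomness.

The package works with *Streptococcus* CRISPR spacer amplicon data: paired-end
FASTQ reads produced with fusion primers that anneal inside the CRISPR repeat,
per-sample spacer count tables, qPCR copy-number tables, and sample metadata
(individual, household, sample type, dilution).

Everything random in the repository flows through :func:`derive_seed` /
``numpy.random.Generator`` objects created from an explicit integer seed, so
identical seed + configuration reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "ReadPair",
    "PrimerSet",
    "SampleMetadata",
    "CopyRecord",
    "CopyTable",
    "CRISPR3",
    "CRISPR1",
    "PRIMER_SETS",
    "DEFAULT_LOQ",
    "revcomp",
    "hamming",
    "derive_seed",
    "get_logger",
    "load_config",
    "read_fastq",
    "write_fastq",
    "read_metadata",
    "read_copy_table",
    "read_asv_table",
    "write_asv_table",
]

DNA_ALPHABET = set("ACGTN")

#: Lowest concentration on the qPCR calibration curve, copies/uL.
DEFAULT_LOQ = 100.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a stream-specific child seed (< 2**31) from a master seed.

    Stable across runs and platforms (BLAKE2 of the token string), so each
    sample / replicate gets an independent but reproducible generator.
    """
    key = ":".join([str(int(seed))] + [str(t) for t in tokens]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


def get_logger(name: str = "metacrispr") -> logging.Logger:
    """Package logger writing to standard error.

    Only the package root logger carries the handler; module loggers
    propagate to it, so each event is emitted once.
    """
    root = logging.getLogger("metacrispr")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logging.getLogger(name)


log = get_logger()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Read:
    """A single sequencing read with per-base Phred quality scores."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if any(q < 0 for q in self.qual):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """Mated R1/R2 reads; id stems must match after mate-suffix stripping."""

    r1: Read
    r2: Read

    def __post_init__(self) -> None:
        if _id_stem(self.r1.id) != _id_stem(self.r2.id):
            raise ValueError(
                f"unmated reads: {self.r1.id!r} vs {self.r2.id!r}"
            )

    @property
    def id(self) -> str:
        return _id_stem(self.r1.id)


def _id_stem(read_id: str) -> str:
    """Strip common mate suffixes (``/1``, ``/2``, `` 1:...``, `` 2:...``)."""
    stem = read_id.split()[0] if read_id else read_id
    if stem.endswith(("/1", "/2")):
        stem = stem[:-2]
    return stem


@dataclass(frozen=True)
class PrimerSet:
    """Fusion-primer definition for one CRISPR locus.

    The sequencing primers are Illumina overhang tails fused to locus-specific
    parts that anneal inside the CRISPR repeat, so the amplified insert between
    them is a single spacer (20-40 nt).
    """

    locus_name: str
    fwd_locus: str
    rev_locus: str
    fwd_tail: str = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
    rev_tail: str = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"
    min_spacer_len: int = 20
    max_spacer_len: int = 40

    def __post_init__(self) -> None:
        if not (0 < self.min_spacer_len <= self.max_spacer_len):
            raise ValueError("invalid spacer length bounds")
        for name in ("fwd_locus", "rev_locus", "fwd_tail", "rev_tail"):
            seq = getattr(self, name)
            if not seq or not set(seq) <= DNA_ALPHABET:
                raise ValueError(f"{name} is not a DNA string: {seq!r}")

    @property
    def fwd_fusion(self) -> str:
        """Full forward fusion primer: Illumina tail + locus part."""
        return self.fwd_tail + self.fwd_locus

    @property
    def rev_fusion(self) -> str:
        """Full reverse fusion primer: Illumina tail + locus part."""
        return self.rev_tail + self.rev_locus


#: Sequencing primer set targeting the Streptococcus CRISPR3 repeat.
CRISPR3 = PrimerSet(
    locus_name="CRISPR3",
    fwd_locus="TCGAAACAACACAGCTCTAAAAC",
    rev_locus="TGTTGTTTCGAATGGTTCCAAAAC",
)

#: Sequencing primer set targeting the Streptococcus CRISPR1 repeat.
CRISPR1 = PrimerSet(
    locus_name="CRISPR1",
    fwd_locus="ACTCTCAAGATTTAAGTAACTGTACAAC",
    rev_locus="CAGTTACTTAAATCTTGAGAGTACAAAAAC",
)

PRIMER_SETS: dict[str, PrimerSet] = {"CRISPR3": CRISPR3, "CRISPR1": CRISPR1}

SAMPLE_TYPES = ("skin", "saliva", "object", "NTC", "standard")


@dataclass(frozen=True)
class SampleMetadata:
    """Provenance of one sequencing/qPCR sample."""

    sample_id: str
    individual: str  # empty for NTC samples
    household: str = ""
    sample_type: str = "skin"
    site: str = ""
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.sample_type == "NTC" and self.individual:
            raise ValueError(f"NTC sample {self.sample_id!r} must have no individual")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")


@dataclass(frozen=True)
class CopyRecord:
    """One qPCR quantification row: spacer copies/uL for one sample x locus.

    ``copies_per_ul is None`` encodes ND (no amplification in either
    replicate), which is representationally distinct from a measured value
    below the limit of quantification.
    """

    sample_id: str
    locus: str
    copies_per_ul: float | None
    below_loq: bool
    bacterial_dna_pg_ul: float | None = None
    human_dna_pg_ul: float | None = None

    def __post_init__(self) -> None:
        if self.copies_per_ul is not None and self.copies_per_ul < 0:
            raise ValueError(
                f"{self.sample_id}/{self.locus}: negative copies/uL"
            )

    @property
    def nd(self) -> bool:
        return self.copies_per_ul is None

    def numeric_copies(self) -> float:
        """Copies/uL with ND mapped to 0 (the convention used in summaries)."""
        return 0.0 if self.copies_per_ul is None else self.copies_per_ul


class CopyTable:
    """Collection of :class:`CopyRecord` rows with uniqueness validation."""

    def __init__(self, records: Iterable[CopyRecord], loq: float = DEFAULT_LOQ):
        self.records: list[CopyRecord] = list(records)
        self.loq = float(loq)
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.locus)
            if key in seen:
                raise ValueError(f"duplicate copy-table row {key}")
            seen.add(key)
            expected_flag = rec.nd or rec.numeric_copies() < self.loq
            if rec.below_loq != expected_flag:
                raise ValueError(
                    f"{key}: below_loq flag {rec.below_loq} inconsistent with "
                    f"value {rec.copies_per_ul} at LOQ {self.loq}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CopyRecord]:
        return iter(self.records)

    def select(self, sample_ids: Sequence[str] | None = None, locus: str | None = None) -> list[CopyRecord]:
        out = []
        for rec in self.records:
            if sample_ids is not None and rec.sample_id not in sample_ids:
                continue
            if locus is not None and rec.locus != locus:
                continue
            out.append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "locus": [r.locus for r in self.records],
                "copies_per_ul": [r.copies_per_ul for r in self.records],
                "below_loq": [r.below_loq for r in self.records],
                "bacterial_dna_pg_ul": [r.bacterial_dna_pg_ul for r in self.records],
                "human_dna_pg_ul": [r.human_dna_pg_ul for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def read_fastq(source: str | Path | IO[str]) -> Iterator[Read]:
    """Stream Phred+33 FASTQ records as :class:`Read` objects.

    Malformed records (missing ``@``/``+`` markers, length mismatch,
    truncation) raise ``ValueError`` naming the 1-based record index.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt") as handle:
            yield from _parse_fastq(handle)
    else:
        yield from _parse_fastq(source)


def _parse_fastq(handle: IO[str]) -> Iterator[Read]:
    # Biopython does the 4-line framing; we add record-indexed errors and
    # alphabet/score validation on top.
    iterator = FastqGeneralIterator(handle)
    index = 0
    while True:
        index += 1
        try:
            title, seq, qual = next(iterator)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"FASTQ record {index}: {exc}") from exc
        if len(seq) != len(qual):
            raise ValueError(
                f"FASTQ record {index}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        seq = seq.upper()
        if not set(seq) <= DNA_ALPHABET:
            raise ValueError(f"FASTQ record {index}: non-DNA characters in sequence")
        scores = tuple(ord(c) - 33 for c in qual)
        if any(s < 0 for s in scores):
            raise ValueError(f"FASTQ record {index}: quality character below '!'")
        yield Read(id=title, seq=seq, qual=scores)


def write_fastq(reads: Iterable[Read], dest: str | Path | IO[str]) -> None:
    """Write reads as Phred+33 FASTQ; round-trips exactly with read_fastq."""
    if isinstance(dest, (str, Path)):
        with open(dest, "wt") as handle:
            _write_fastq(reads, handle)
    else:
        _write_fastq(reads, dest)


def _write_fastq(reads: Iterable[Read], handle: IO[str]) -> None:
    for read in reads:
        qual = "".join(chr(q + 33) for q in read.qual)
        handle.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_ND_TOKENS = {"ND", "nd", "NA", ""}
#: Suffix used in copy tables to mark a measured value below the LOQ.
BELOW_LOQ_MARK = "*"


def _parse_copies(token: str, loq: float) -> tuple[float | None, bool]:
    token = str(token).strip().replace(",", "")
    if token in _ND_TOKENS:
        return None, True
    flagged = token.endswith(BELOW_LOQ_MARK)
    value = float(token.rstrip(BELOW_LOQ_MARK))
    if value < 0:
        raise ValueError(f"negative copies/uL: {token!r}")
    return value, flagged or value < loq


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-separated table with a header row."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")


def read_metadata(path: str | Path, loq: float = DEFAULT_LOQ) -> tuple[list[SampleMetadata], CopyTable]:
    """Parse a combined sample-metadata + copy-number table.

    Expected columns: ``sample_id, individual, household, sample_type, site,
    dilution_factor, locus, copies_per_ul[, bacterial_dna_pg_ul,
    human_dna_pg_ul]``. One row per sample x locus; ``ND`` marks no
    amplification and a trailing ``*`` marks a value below the LOQ.
    """
    df = _read_table(path)
    required = {"sample_id", "individual", "sample_type", "locus", "copies_per_ul"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")

    meta: dict[str, SampleMetadata] = {}
    records: list[CopyRecord] = []
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid not in meta:
            meta[sid] = SampleMetadata(
                sample_id=sid,
                individual=row["individual"].strip(),
                household=row.get("household", "").strip(),
                sample_type=row["sample_type"].strip(),
                site=row.get("site", "").strip(),
                dilution_factor=float(row.get("dilution_factor", "") or 1.0),
            )
        copies, below = _parse_copies(row["copies_per_ul"], loq)
        records.append(
            CopyRecord(
                sample_id=sid,
                locus=row["locus"].strip(),
                copies_per_ul=copies,
                below_loq=below,
                bacterial_dna_pg_ul=_opt_float(row.get("bacterial_dna_pg_ul", "")),
                human_dna_pg_ul=_opt_float(row.get("human_dna_pg_ul", "")),
            )
        )
    return list(meta.values()), CopyTable(records, loq=loq)


def read_copy_table(path: str | Path, loq: float = DEFAULT_LOQ) -> CopyTable:
    """Parse only the copy-number part of a metadata/copy table."""
    _, table = read_metadata(path, loq=loq)
    return table


def _opt_float(token: str) -> float | None:
    token = str(token).strip().replace(",", "")
    return None if token in _ND_TOKENS else float(token)


def read_asv_table(path: str | Path):
    """Read an ASV table TSV (rows = ASV sequences, columns = samples)."""
    from .asv_denoise import ASVTable

    return ASVTable.from_tsv(path)


def write_asv_table(table, path: str | Path) -> None:
    """Write an ASV table TSV; round-trips exactly with read_asv_table."""
    table.to_tsv(path)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a structured (YAML) configuration file into a flat dict."""
    with open(path, "rt") as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config
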