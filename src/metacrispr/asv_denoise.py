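"""Collapse spacer observations into amplicon sequence variants (ASVs).

Full error-rate learning (as done by dedicated amplicon denoisers) is not
re-implemented here. Because the discriminative signal of spacer typing is
the presence and abundance of exact 20-40 nt sequences, a simpler abundance
-ratio rule suffices: within each sample, a low-abundance sequence one
substitution away from a sequence at least ``min_fold`` times more abundant
is treated as a sequencing/PCR error of that parent and merged into it.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import get_logger
from .spacer_extract import SpacerObservation

__all__ = ["ASVTable", "dereplicate", "collapse_errors", "drop_empty", "denoise"]

log = get_logger(__name__)


class ASVTable:
    """Samples x unique-spacer-sequence count matrix.

    The canonical ordering is: samples in insertion order; ASV columns by
    descending total count, ties broken by sequence lexicographic order.
    Serialization (TSV, rows = ASV sequences, columns = samples) round-trips
    exactly.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.columns.duplicated().any():
            raise ValueError("duplicate ASV sequences in table")
        if counts.index.duplicated().any():
            raise ValueError("duplicate sample ids in table")
        values = counts.to_numpy()
        if values.size and (
            not np.issubdtype(values.dtype, np.integer) or (values < 0).any()
        ):
            raise ValueError("ASV counts must be non-negative integers")
        self.counts = counts.astype(np.int64) if values.size else counts.astype(np.int64)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_observations(cls, observations: Iterable[SpacerObservation]) -> "ASVTable":
        per_sample: dict[str, Counter] = {}
        for obs in observations:
            per_sample.setdefault(obs.sample_id, Counter())[obs.seq] += obs.count
        return cls.from_counts(per_sample)

    @classmethod
    def from_counts(cls, per_sample: Mapping[str, Mapping[str, int]]) -> "ASVTable":
        sample_ids = list(per_sample)
        sequences: list[str] = []
        seen: set[str] = set()
        for counts in per_sample.values():
            for seq in counts:
                if seq not in seen:
                    seen.add(seq)
                    sequences.append(seq)
        df = pd.DataFrame(0, index=sample_ids, columns=sequences, dtype=np.int64)
        for sid, counts in per_sample.items():
            for seq, c in counts.items():
                df.loc[sid, seq] = c
        table = cls(df)
        table._canonicalize()
        return table

    # -- basic protocol ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sequences(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts.loc[sample_id].to_numpy()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ASVTable) and self.counts.equals(other.counts)

    def _canonicalize(self) -> None:
        if self.counts.shape[1]:
            totals = self.counts.sum(axis=0)
            order = sorted(self.counts.columns, key=lambda s: (-totals[s], s))
            self.counts = self.counts[order]

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.T
        out.index.name = "sequence"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ASVTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        for col in df.columns:
            values = pd.to_numeric(df[col], errors="raise")
            if not (values == values.astype(np.int64)).all():
                raise ValueError(f"non-integer count in column {col!r}")
            df[col] = values.astype(np.int64)
        if df.index.duplicated().any():
            raise ValueError("duplicate ASV sequence rows")
        table = cls(df.T)
        table.counts.index.name = None
        table.counts.columns.name = None
        return table


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def dereplicate(observations: Iterable[SpacerObservation]) -> ASVTable:
    """One ASV column per distinct exact sequence; counts summed per sample."""
    return ASVTable.from_observations(observations)


def _within_hamming(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def _collapse_sample(counts: dict[str, int], min_fold: float, max_hamming: int) -> dict[str, int]:
    """Greedy per-sample merge to fixed point.

    Children are visited in ascending abundance; each is merged into the most
    abundant qualifying parent (abundance ratio >= min_fold, Hamming distance
    <= max_hamming). Ties between parents prefer the higher count, then the
    lexicographically smaller sequence. Repeats until no merge applies.
    Substitution-only errors preserve length, so candidate parents are looked
    up in per-length buckets.
    """
    counts = {s: c for s, c in counts.items() if c > 0}
    changed = True
    while changed:
        changed = False
        buckets: dict[int, list[str]] = {}
        for seq in counts:
            buckets.setdefault(len(seq), []).append(seq)
        order = sorted(counts, key=lambda s: (counts[s], s))  # children first
        for child in order:
            c_count = counts.get(child, 0)
            if c_count == 0:
                continue
            best: tuple[int, str] | None = None
            for parent in buckets[len(child)]:
                p_count = counts.get(parent, 0)
                if parent == child or p_count < c_count * min_fold:
                    continue
                if not _within_hamming(parent, child, max_hamming):
                    continue
                if best is None or (-p_count, parent) < (-best[0], best[1]):
                    best = (p_count, parent)
            if best is not None:
                counts[best[1]] += c_count
                del counts[child]
                changed = True
    return counts


def collapse_errors(table: ASVTable, min_fold: float = 32, max_hamming: int = 1) -> ASVTable:
    """Merge likely error sequences into abundant parents, per sample.

    Per-sample total counts are conserved; zeroed columns are retained (use
    :func:`drop_empty` to remove them).
    """
    merged: dict[str, dict[str, int]] = {}
    for sample_id in table.sample_ids:
        row = table.counts.loc[sample_id]
        counts = {seq: int(c) for seq, c in row.items() if c > 0}
        merged[sample_id] = _collapse_sample(counts, min_fold, max_hamming)

    out = pd.DataFrame(0, index=table.counts.index, columns=table.counts.columns, dtype=np.int64)
    for sample_id, counts in merged.items():
        for seq, c in counts.items():
            out.loc[sample_id, seq] = c
    result = ASVTable(out)
    result._canonicalize()
    return result


def drop_empty(table: ASVTable) -> ASVTable:
    """Remove all-zero ASV columns; all-zero sample rows are retained."""
    keep = table.counts.columns[(table.counts != 0).any(axis=0)]
    return ASVTable(table.counts[keep])


def denoise(
    observations: Iterable[SpacerObservation],
    min_fold: float = 32,
    max_hamming: int = 1,
) -> ASVTable:
    """dereplicate -> collapse_errors -> drop_empty convenience pipeline."""
    table = dereplicate(observations)
    table = collapse_errors(table, min_fold=min_fold, max_hamming=max_hamming)
    return drop_empty(table)
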