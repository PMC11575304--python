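"""Turn raw paired-end amplicon reads into per-sample spacer observations.

Each read pair is processed through: quality trimming (modified-Mott),
repeat-primer removal from both mates, read-through trimming into the
opposite primer, mate reconciliation, primer-dimer/artifact classification,
and the 20-40 nt spacer length filter. Every pair receives exactly one
:class:`ArtifactLabel`, so label counts always sum to the input pair count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from .io_core import PrimerSet, Read, ReadPair, get_logger, read_fastq, revcomp

__all__ = [
    "ArtifactLabel",
    "SpacerObservation",
    "ExtractParams",
    "quality_trim",
    "find_and_trim_primer",
    "reconcile_pair",
    "length_filter",
    "classify_artifact",
    "extract_read_pair",
    "extract_sample",
]

log = get_logger(__name__)


class ArtifactLabel(str, Enum):
    """Outcome label assigned to every processed read pair."""

    OK = "ok"
    PRIMER_DIMER_FWD = "primer_dimer_fwd"
    PRIMER_DIMER_REV_TAIL = "primer_dimer_rev_tail"
    NO_PRIMER_FOUND = "no_primer_found"
    LENGTH_FAIL = "length_fail"
    QUALITY_FAIL = "quality_fail"
    PAIR_CONFLICT = "pair_conflict"


@dataclass(frozen=True)
class SpacerObservation:
    """A distinct spacer sequence observed ``count`` times in one sample."""

    sample_id: str
    seq: str
    count: int


@dataclass(frozen=True)
class ExtractParams:
    """Tunable knobs of the extraction pipeline."""

    error_limit: float = 0.01  # Mott trimming limit, Q20-equivalent
    max_mismatch: int = 2  # substitutions tolerated in the primer prefix
    readthrough_seed: int = 12  # min match into the opposite primer to trim
    min_len: int = 20
    max_len: int = 40


# ---------------------------------------------------------------------------
# Quality trimming (modified Mott)
# ---------------------------------------------------------------------------


def _mott_window(qual: Sequence[int], error_limit: float) -> tuple[int, int]:
    """Best-scoring contiguous window under the modified-Mott criterion.

    Each base contributes ``error_limit - 10**(-Q/10)``; the window with the
    maximal cumulative score is kept. Ties prefer the smaller start, then the
    larger end (longest window). The empty window (0, 0) scores 0, so a read
    whose bases all score negative trims to empty.
    """
    best_sum = 0.0
    best = (0, 0)
    run_sum = 0.0
    run_start = 0
    for j, q in enumerate(qual):
        score = error_limit - 10.0 ** (-q / 10.0)
        if run_sum < 0.0:
            # A strictly negative prefix can never help; restart after it.
            run_sum = score
            run_start = j
        else:
            run_sum += score
        if run_sum > best_sum or (
            run_sum == best_sum
            and (run_start < best[0] or (run_start == best[0] and j + 1 > best[1]))
        ):
            best_sum = run_sum
            best = (run_start, j + 1)
    return best


def quality_trim(read: Read, error_limit: float = 0.01) -> Read:
    """Trim a read to its maximal-score subread (possibly empty)."""
    start, end = _mott_window(read.qual, error_limit)
    return Read(id=read.id, seq=read.seq[start:end], qual=read.qual[start:end])


# ---------------------------------------------------------------------------
# Primer handling
# ---------------------------------------------------------------------------


def _prefix_mismatches(seq: str, primer: str, limit: int) -> int | None:
    """Mismatches between ``primer`` and the same-length prefix of ``seq``.

    Returns None when the prefix is shorter than the primer or exceeds
    ``limit`` mismatches (early exit).
    """
    if len(seq) < len(primer):
        return None
    mismatches = 0
    for a, b in zip(seq, primer):
        if a != b:
            mismatches += 1
            if mismatches > limit:
                return None
    return mismatches


def find_and_trim_primer(seq: str, primer: str, max_mismatch: int = 2) -> str | None:
    """Remove ``primer`` from the start of ``seq`` (substitutions only).

    Returns the remainder, or None if the prefix differs from the primer by
    more than ``max_mismatch`` substitutions (indels are not modelled).
    """
    if len(primer) < 12:
        raise ValueError("primer must be at least 12 nt")
    if _prefix_mismatches(seq, primer, max_mismatch) is None:
        return None
    return seq[len(primer):]


def _trim_readthrough(seq: str, opposite: str, seed_len: int = 12) -> str:
    """Cut ``seq`` where it reads through into the opposite primer.

    Scans for the leftmost position whose suffix matches a prefix of
    ``opposite`` with at least ``seed_len`` aligned bases and <= 1 mismatch in
    the seed. Shorter trailing overlaps are left in place (they then fail the
    length filter downstream).
    """
    n = len(seq)
    seed = opposite[:seed_len]
    for i in range(0, n - seed_len + 1):
        window = seq[i : i + seed_len]
        mm = 0
        for a, b in zip(window, seed):
            if a != b:
                mm += 1
                if mm > 1:
                    break
        if mm <= 1:
            return seq[:i]
    return seq


# ---------------------------------------------------------------------------
# Pair reconciliation
# ---------------------------------------------------------------------------


def reconcile_pair(
    insert1: str,
    insert2_revcomp: str,
    quals: tuple[Sequence[int], Sequence[int]] | None = None,
) -> str | None:
    """Merge the two mate-derived inserts into one spacer sequence.

    Both arguments must be in the same (forward-primer) orientation. Equal
    sequences pass through; a single mismatch is resolved toward the base
    with the higher Phred score (R1 wins ties); anything else — including a
    length difference — is a pair conflict (None).
    """
    if len(insert1) != len(insert2_revcomp):
        return None
    if insert1 == insert2_revcomp:
        return insert1
    mismatches = [i for i, (a, b) in enumerate(zip(insert1, insert2_revcomp)) if a != b]
    if len(mismatches) > 1:
        return None
    i = mismatches[0]
    if quals is None:
        return insert1
    q1, q2 = quals
    winner = insert1[i] if q1[i] >= q2[i] else insert2_revcomp[i]
    return insert1[:i] + winner + insert1[i + 1 :]


def length_filter(seq: str, min_len: int = 20, max_len: int = 40) -> bool:
    """Keep iff ``min_len <= len(seq) <= max_len`` (inclusive bounds)."""
    return min_len <= len(seq) <= max_len


# ---------------------------------------------------------------------------
# Artifact classification
# ---------------------------------------------------------------------------


def _matches_with_mismatches(window: str, target: str, limit: int = 1) -> bool:
    mm = 0
    for a, b in zip(window, target):
        if a != b:
            mm += 1
            if mm > limit:
                return False
    return True


def classify_artifact(seq: str, primers: PrimerSet, min_match: int = 15) -> ArtifactLabel:
    """Label primer-dimer-derived inserts.

    Primer dimers leave inserts that are fragments of the primers themselves:
    either the reverse complement of the insert matches the 5' end of an
    Illumina tail (reverse-primer dimer) or the insert is a substring of a
    fusion primer (forward-primer dimer). Matches require >= ``min_match``
    aligned bases with <= 1 mismatch.
    """
    if len(seq) >= min_match:
        rc = revcomp(seq)
        for tail in (primers.rev_tail, primers.fwd_tail):
            k = min(len(rc), len(tail))
            if k >= min_match and _matches_with_mismatches(rc[:k], tail[:k]):
                return ArtifactLabel.PRIMER_DIMER_REV_TAIL
        for fusion in (primers.fwd_fusion, primers.rev_fusion):
            if len(seq) <= len(fusion):
                for i in range(len(fusion) - len(seq) + 1):
                    if _matches_with_mismatches(fusion[i : i + len(seq)], seq):
                        return ArtifactLabel.PRIMER_DIMER_FWD
    return ArtifactLabel.OK


# ---------------------------------------------------------------------------
# Full per-pair pipeline
# ---------------------------------------------------------------------------


def extract_read_pair(
    pair: ReadPair, primers: PrimerSet, params: ExtractParams = ExtractParams()
) -> tuple[ArtifactLabel, str | None]:
    """Process one read pair; returns (label, spacer sequence or None)."""
    r1 = quality_trim(pair.r1, params.error_limit)
    r2 = quality_trim(pair.r2, params.error_limit)
    if len(r1) == 0 or len(r2) == 0:
        return ArtifactLabel.QUALITY_FAIL, None

    rem1 = find_and_trim_primer(r1.seq, primers.fwd_locus, params.max_mismatch)
    rem2 = find_and_trim_primer(r2.seq, primers.rev_locus, params.max_mismatch)
    if rem1 is None or rem2 is None:
        return ArtifactLabel.NO_PRIMER_FOUND, None
    qual1 = r1.qual[len(primers.fwd_locus):]
    qual2 = r2.qual[len(primers.rev_locus):]

    # R1 reads through the insert into the reverse primer site (and vice
    # versa for R2) because spacer amplicons are shorter than the read.
    ins1 = _trim_readthrough(rem1, revcomp(primers.rev_locus), params.readthrough_seed)
    ins2 = _trim_readthrough(rem2, revcomp(primers.fwd_locus), params.readthrough_seed)
    qual1 = qual1[: len(ins1)]
    qual2 = qual2[: len(ins2)]

    spacer = reconcile_pair(ins1, revcomp(ins2), (qual1, qual2[::-1]))
    if spacer is None:
        return ArtifactLabel.PAIR_CONFLICT, None

    dimer = classify_artifact(spacer, primers)
    if dimer is not ArtifactLabel.OK:
        return dimer, None
    if "N" in spacer:
        return ArtifactLabel.QUALITY_FAIL, None
    if not length_filter(spacer, params.min_len, params.max_len):
        return ArtifactLabel.LENGTH_FAIL, None
    return ArtifactLabel.OK, spacer


def extract_sample(
    fastq_r1: str | Path | IO[str] | Iterable[Read],
    fastq_r2: str | Path | IO[str] | Iterable[Read],
    primers: PrimerSet,
    params: ExtractParams = ExtractParams(),
    sample_id: str = "sample",
) -> tuple[list[SpacerObservation], Counter]:
    """Extract spacers from mated FASTQ inputs.

    Returns per-sample spacer observations aggregated to (sequence, count)
    and a per-label report; the report conserves reads (labels sum to the
    number of input pairs). Identical read pairs are processed once and
    weighted by multiplicity, which makes deep amplicon samples cheap.
    """
    reads1 = fastq_r1 if _is_read_iter(fastq_r1) else read_fastq(fastq_r1)
    reads2 = fastq_r2 if _is_read_iter(fastq_r2) else read_fastq(fastq_r2)

    groups: Counter = Counter()
    exemplars: dict = {}
    n_pairs = 0
    for r1, r2 in _zip_mates(reads1, reads2):
        pair = ReadPair(r1, r2)
        key = (r1.seq, r1.qual, r2.seq, r2.qual)
        groups[key] += 1
        if key not in exemplars:
            exemplars[key] = pair
        n_pairs += 1

    report: Counter = Counter({label: 0 for label in ArtifactLabel})
    spacer_counts: Counter = Counter()
    for key, count in groups.items():
        label, spacer = extract_read_pair(exemplars[key], primers, params)
        report[label] += count
        if spacer is not None:
            spacer_counts[spacer] += count

    assert sum(report.values()) == n_pairs, "label counts must conserve reads"
    log.info(
        "%s: %d pairs in, %d spacer reads out (%d distinct)",
        sample_id, n_pairs, report[ArtifactLabel.OK], len(spacer_counts),
    )
    observations = [
        SpacerObservation(sample_id=sample_id, seq=seq, count=c)
        for seq, c in sorted(spacer_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return observations, report


def _is_read_iter(source) -> bool:
    if isinstance(source, (str, Path)) or hasattr(source, "read"):
        return False
    return True


def _zip_mates(reads1: Iterable[Read], reads2: Iterable[Read]) -> Iterator[tuple[Read, Read]]:
    it1, it2 = iter(reads1), iter(reads2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise ValueError("unmated FASTQ inputs: different record counts")
        yield r1, r2
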