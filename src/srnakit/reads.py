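"""Read cleaning: quality model, adapter/poly-A/length filters, tag collapsing.

The quality model is the Solexa odds mapping between a per-base quality
score sQ in [0, 41] and a sequencing error probability E:

    sQ = -10 * log10(E / (1 - E))        (score from error)
    Y  = 10 ** (-sQ / 10);  E = Y/(1+Y)  (error from score)

Note this is the *odds* (Solexa) transform, not the plain Phred one: at
sQ = 0 it gives E = 0.5, and E is bounded above by 0.5 for sQ >= 0.

Cleaning applies, in order, per read: (1) the quality floor (mean per-base
error over the read must not exceed the floor's equivalent error), (2) 3'
adapter clipping (exact full-adapter suffix, then progressively shorter
adapter prefixes down to 6 nt at the read end), (3) the poly-A rule
(>= 80% A after clipping), (4) length bounds (default 18-30 nt). Each read
is tallied under the first rule it fails, so the tally plus the kept reads
exactly partition the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple, Union

import numpy as np

from ._seq import to_rna

__all__ = [
    "quality_to_error",
    "error_to_quality",
    "phred_string_to_scores",
    "mean_error_probability",
    "clip_adapter",
    "clean_reads",
    "CleanResult",
    "SmallRNATag",
    "collapse_tags",
    "length_distribution",
]

REJECT_LOW_QUALITY = "low_quality"
REJECT_TOO_SHORT = "too_short"
REJECT_TOO_LONG = "too_long"
REJECT_POLY_A = "poly_a"
KEPT = "kept"


def quality_to_error(sq):
    """Error probability E from quality score sQ (Solexa odds mapping).

    Accepts scalars or arrays; E = Y/(1+Y) with Y = 10^(-sQ/10), so
    E(0) = 0.5 and E decreases monotonically in sQ.
    """
    sq_arr = np.asarray(sq, dtype=float)
    if np.any(sq_arr < 0):
        raise ValueError("quality score must be non-negative")
    y = 10.0 ** (-sq_arr / 10.0)
    e = y / (1.0 + y)
    return float(e) if np.isscalar(sq) or sq_arr.ndim == 0 else e


def error_to_quality(e):
    """Quality score sQ = -10*log10(E/(1-E)) for E in (0, 1)."""
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr <= 0) or np.any(e_arr >= 1):
        raise ValueError("error probability must lie strictly in (0, 1)")
    sq = -10.0 * np.log10(e_arr / (1.0 - e_arr))
    return float(sq) if np.isscalar(e) or e_arr.ndim == 0 else sq


def phred_string_to_scores(qual: str) -> np.ndarray:
    """Sanger Phred+33 quality string to an integer score array."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - 33.0


def mean_error_probability(qual: str) -> float:
    """Mean per-base error probability of a Phred+33 quality string."""
    return float(np.mean(quality_to_error(phred_string_to_scores(qual))))


def clip_adapter(seq: str, adapter: str, min_overlap: int = 6) -> Tuple[str, bool]:
    """Remove a 3' adapter occurring as a read suffix.

    Tries the full adapter first, then successively shorter adapter
    prefixes (down to ``min_overlap`` nt) anchored at the read end; exact
    matches only. Returns (insert, found).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    for k in range(len(adapter), min_overlap - 1, -1):
        if len(seq) >= k and seq.endswith(adapter[:k]):
            return seq[: len(seq) - k], True
    return seq, False


@dataclass
class CleanResult:
    """Clean inserts plus a rejection tally partitioning the input reads."""

    reads: List[str]
    tally: Dict[str, int]

    @property
    def n_input(self) -> int:
        return sum(self.tally.values())


class FastqFormatError(ValueError):
    pass


def _iter_read_records(
    reads: Union[str, Iterable]
) -> Iterator[Tuple[str, str]]:
    """Yield (sequence, quality-string) from a FASTQ path or an iterable
    of (seq, qual) pairs."""
    if isinstance(reads, str):
        from .io import read_fastq

        for _rid, seq, qual in read_fastq(reads):
            yield seq, qual
    else:
        for rec in reads:
            if len(rec) == 3:
                _rid, seq, qual = rec
            else:
                seq, qual = rec
            yield seq, qual


def clean_reads(
    reads: Union[str, Iterable],
    adapter: str,
    min_len: int = 18,
    max_len: int = 30,
    quality_floor: float = 20.0,
    polya_fraction: float = 0.8,
    min_adapter_overlap: int = 6,
) -> CleanResult:
    """Quality-filter, adapter-clip and length-filter a small-RNA library.

    ``reads`` is a FASTQ path or an iterable of (seq, qual) / (id, seq,
    qual) records. The quality floor is a score; reads whose mean per-base
    error exceeds ``quality_to_error(quality_floor)`` are rejected. Reads
    with no recognizable adapter are kept unclipped (the insert may span
    the full read). Returns clean insert sequences (DNA space, as
    sequenced) and the rejection tally.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    max_mean_error = quality_to_error(quality_floor)
    tally = {
        REJECT_LOW_QUALITY: 0,
        REJECT_POLY_A: 0,
        REJECT_TOO_SHORT: 0,
        REJECT_TOO_LONG: 0,
        KEPT: 0,
    }
    kept: List[str] = []
    for idx, (seq, qual) in enumerate(_iter_read_records(reads)):
        seq = seq.upper()
        if len(qual) != len(seq):
            raise FastqFormatError(
                f"record {idx}: sequence and quality lengths differ"
            )
        if mean_error_probability(qual) > max_mean_error:
            tally[REJECT_LOW_QUALITY] += 1
            continue
        insert, _found = clip_adapter(seq, adapter, min_adapter_overlap)
        if insert and insert.count("A") / len(insert) >= polya_fraction:
            tally[REJECT_POLY_A] += 1
            continue
        if len(insert) < min_len:
            tally[REJECT_TOO_SHORT] += 1
            continue
        if len(insert) > max_len:
            tally[REJECT_TOO_LONG] += 1
            continue
        tally[KEPT] += 1
        kept.append(insert)
    return CleanResult(reads=kept, tally=tally)


@dataclass(frozen=True)
class SmallRNATag:
    """A unique clean-read sequence with its per-library counts.

    Sequences are stored in RNA space (T converted to U on ingest).
    """

    sequence: str
    count_a: int = 0
    count_b: int = 0

    @property
    def total(self) -> int:
        return self.count_a + self.count_b

    def __post_init__(self):
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("tag counts must be non-negative")


def collapse_tags(
    clean_a: Sequence[str], clean_b: Sequence[str] = ()
) -> List[SmallRNATag]:
    """Collapse clean reads of two libraries into unique tags with counts.

    Output is sorted by total count descending, ties broken
    lexicographically by sequence, so it is invariant to read order.
    """
    counts_a = Counter(to_rna(s) for s in clean_a)
    counts_b = Counter(to_rna(s) for s in clean_b)
    tags = [
        SmallRNATag(seq, counts_a.get(seq, 0), counts_b.get(seq, 0))
        for seq in set(counts_a) | set(counts_b)
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def length_distribution(
    tags: Sequence[SmallRNATag], min_len: int = 18, max_len: int = 30
):
    """Read-count-weighted length histogram as fractions summing to 1.

    Weighted by counts (total reads), not unique tags; lengths outside
    the range are clipped into the terminal bins.
    """
    import pandas as pd

    lengths = np.arange(min_len, max_len + 1)
    weights = np.zeros(len(lengths), dtype=float)
    for tag in tags:
        li = int(np.clip(len(tag.sequence), min_len, max_len)) - min_len
        weights[li] += tag.total
    total = weights.sum()
    if total > 0:
        weights /= total
    return pd.Series(weights, index=lengths, name="fraction")
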