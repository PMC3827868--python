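"""Hierarchical ncRNA annotation and <=1-mismatch genome mapping.

Tags are first matched (exact substring) against contaminant ncRNA
references in a fixed priority order (rRNA > tRNA > snRNA > snoRNA >
repeat), then optionally against transcript sequences (mRNA fragments);
a tag matching several classes keeps the highest-priority one. Remaining
tags are unannotated and proceed to miRNA analysis.

Genome mapping reports every occurrence of a tag on either strand with at
most one substitution (no indels). The index is a k-mer seed table
(k = 9): any alignment of an 18+ nt tag with <= 1 mismatch leaves at
least one of the two disjoint 9-mers at tag positions [0,9) and [9,18)
exact (pigeonhole), so seeding on both and verifying by Hamming distance
is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._seq import revcomp_dna, to_dna
from .reads import SmallRNATag

__all__ = [
    "CATEGORY_PRIORITY",
    "AnnotationRecord",
    "classify_ncrna",
    "GenomeHit",
    "GenomeIndex",
    "map_to_genome",
    "annotation_summary",
]

CATEGORY_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA_fragment")
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class AnnotationRecord:
    tag: SmallRNATag
    category: str
    hit_id: str = ""


def classify_ncrna(
    tags: Sequence[SmallRNATag],
    contaminant_set: Sequence[Tuple[str, str, str]],
    transcript_set: Optional[Sequence[Tuple[str, str]]] = None,
) -> List[AnnotationRecord]:
    """Assign each tag one annotation category by priority.

    ``contaminant_set`` holds (id, class, sequence) with class among the
    ncRNA categories; ``transcript_set`` holds (id, sequence) mRNAs whose
    exact substrings are degraded fragments. Matching is exact substring
    in RNA space.
    """
    by_class: Dict[str, List[Tuple[str, str]]] = {c: [] for c in CATEGORY_PRIORITY}
    for cid, cls, seq in contaminant_set:
        if cls not in by_class:
            raise ValueError(f"unknown contaminant class: {cls!r}")
        by_class[cls].append((cid, seq.upper().replace("T", "U")))
    for tid, seq in transcript_set or ():
        by_class["mRNA_fragment"].append((tid, seq.upper().replace("T", "U")))

    records = []
    for tag in tags:
        category, hit_id = UNANNOTATED, ""
        for cls in CATEGORY_PRIORITY:
            for rid, refseq in by_class[cls]:
                if tag.sequence in refseq:
                    category, hit_id = cls, rid
                    break
            if category != UNANNOTATED:
                break
        records.append(AnnotationRecord(tag, category, hit_id))
    return records


@dataclass(frozen=True)
class GenomeHit:
    tag_sequence: str  # RNA space, as collapsed
    chrom: str
    start: int  # 0-based on the forward strand
    strand: str  # '+' or '-'
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.tag_sequence)


class GenomeIndex:
    """k-mer seed index over a genome for exhaustive <=1-mismatch mapping."""

    def __init__(self, genome: Union[str, Dict[str, str]], k: int = 9):
        if isinstance(genome, str):
            genome = {"chr1": genome}
        self.k = k
        self.genome = {c: to_dna(s) for c, s in genome.items()}
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def _candidates(self, tag_dna: str) -> Iterable[Tuple[str, int]]:
        k = self.k
        seen = set()
        # two disjoint seeds inside the first 2k bases (tags are >= 18 nt)
        for offset in (0, k):
            seed = tag_dna[offset : offset + k]
            if len(seed) < k:
                continue
            for chrom, pos in self._index.get(seed, ()):
                start = pos - offset
                if start < 0:
                    continue
                if (chrom, start) not in seen:
                    seen.add((chrom, start))
                    yield chrom, start

    def map_tag(self, tag_rna: str, max_mismatch: int = 1) -> List[GenomeHit]:
        tag_dna = to_dna(tag_rna)
        L = len(tag_dna)
        if L < 2 * self.k:
            raise ValueError(f"tag shorter than {2 * self.k} nt cannot be seeded")
        hits = []
        for strand in "+-":
            query = tag_dna if strand == "+" else revcomp_dna(tag_dna)
            for chrom, start in self._candidates(query):
                ref = self.genome[chrom][start : start + L]
                if len(ref) < L:
                    continue
                mm = sum(a != b for a, b in zip(query, ref))
                if mm <= max_mismatch:
                    hits.append(GenomeHit(tag_rna, chrom, start, strand, mm))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.mismatches))
        return hits


def map_to_genome(
    tags: Sequence[Union[SmallRNATag, str]],
    genome: Union[str, Dict[str, str], GenomeIndex],
    max_mismatch: int = 1,
) -> List[GenomeHit]:
    """All genome occurrences of each tag with at most ``max_mismatch``
    substitutions, on both strands."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    hits: List[GenomeHit] = []
    for tag in tags:
        seq = tag.sequence if isinstance(tag, SmallRNATag) else tag
        hits.extend(index.map_tag(seq, max_mismatch))
    return hits


def annotation_summary(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Per-category read and unique-tag counts for both conditions.

    Row sums over categories equal the collapse totals exactly.
    """
    rows: Dict[str, Dict[str, int]] = {}
    for rec in records:
        row = rows.setdefault(
            rec.category, {"reads_a": 0, "reads_b": 0, "unique_tags": 0}
        )
        row["reads_a"] += rec.tag.count_a
        row["reads_b"] += rec.tag.count_b
        row["unique_tags"] += 1
    order = list(CATEGORY_PRIORITY) + [UNANNOTATED]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        [c for c in order if c in rows]
    )
    df.index.name = "category"
    return df
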