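"""File-format helpers: FASTQ/FASTA via Biopython, BED6 and TSV writers."""

from __future__ import annotations

import os
from typing import Iterable, Iterator, List, Sequence, Tuple

from Bio import SeqIO

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_tags_fasta",
    "write_bed6",
]


def read_fastq(path: str) -> Iterator[Tuple[str, str, str]]:
    """Yield (id, sequence, phred+33 quality string) from a FASTQ file.

    A malformed record raises a ValueError naming the index of the record
    at which parsing failed.
    """
    n = 0
    try:
        with open(path) as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                yield rec.id, str(rec.seq), qual
                n += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {n}: {exc}") from exc


def write_fastq(path: str, reads: Iterable[Tuple[str, str, str]]) -> None:
    """Write (id, seq, phred+33 qual) records as Sanger FASTQ."""
    with open(path, "w") as out:
        for rid, seq, qual in reads:
            out.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fasta(path: str) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(path: str, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_tags_fasta(path: str, tags: Sequence) -> None:
    """Collapsed tags as FASTA with ``>tag{n}_x{count_a}_y{count_b}`` headers."""
    write_fasta(
        path,
        (
            (f"tag{i}_x{t.count_a}_y{t.count_b}", t.sequence)
            for i, t in enumerate(tags)
        ),
    )


def write_bed6(path: str, intervals: Iterable[Tuple[str, int, int, str, float, str]]) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as out:
        for chrom, start, end, name, score, strand in intervals:
            out.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
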