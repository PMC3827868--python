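"""Sequence alphabet helpers shared across the pipeline.

Mature miRNAs, precursors and transcripts are handled in RNA space
(A/C/G/U); the genome and raw reads are DNA (A/C/G/T). Conversion happens
once, on ingest.
"""

from __future__ import annotations

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

#: Watson-Crick pairs plus the G:U wobble, in RNA space.
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
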