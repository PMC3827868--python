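"""Reference record types shared by the simulator and the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

__all__ = ["MatureMiRNA", "Precursor", "Contaminant", "ReferenceBundle"]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA product (guide or star strand) on a precursor arm."""

    mature_id: str
    sequence: str  # RNA space
    precursor_id: str = ""
    arm: str = ""  # '5p' or '3p'


@dataclass(frozen=True)
class Precursor:
    """A hairpin precursor with the product coordinates on each arm.

    Coordinates are 0-based half-open on the precursor sequence;
    ``mature_arm`` names the arm carrying the guide strand.
    """

    precursor_id: str
    sequence: str  # RNA space
    arm5_span: Tuple[int, int]
    arm3_span: Tuple[int, int]
    mature_arm: str  # '5p' or '3p'

    def product(self, arm: str) -> str:
        s, e = self.arm5_span if arm == "5p" else self.arm3_span
        return self.sequence[s:e]


@dataclass(frozen=True)
class Contaminant:
    contaminant_id: str
    ncrna_class: str  # rRNA | tRNA | snRNA | snoRNA | repeat
    sequence: str  # RNA space


@dataclass
class ReferenceBundle:
    """Synthetic stand-in for miRBase mature/hairpin sets plus a genome.

    Invariants (checked by the generator's tests): every mature occurs
    verbatim inside exactly one arm of its precursor; every precursor
    occurs verbatim in the genome; mature ids are unique.
    """

    mature_set: List[MatureMiRNA]
    star_set: List[MatureMiRNA]
    precursor_set: List[Precursor]
    contaminant_set: List[Contaminant]
    genome: Dict[str, str]  # DNA space
    precursor_loci: List[Tuple[str, str, int, int]]  # (prec_id, chrom, start, end)
    contaminant_loci: List[Tuple[str, str, int, int]]
    transcript_set: List[Tuple[str, str]] = field(default_factory=list)
    target_truth: List[Tuple[str, str, int, int]] = field(default_factory=list)

    def precursor(self, precursor_id: str) -> Optional[Precursor]:
        for prec in self.precursor_set:
            if prec.precursor_id == precursor_id:
                return prec
        return None

    def all_products(self) -> List[MatureMiRNA]:
        """Guide and star strands together (both arms are sequenced)."""
        return list(self.mature_set) + list(self.star_set)
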