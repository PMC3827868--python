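"""isomiR classification, substitution spectrum, and seed-region edits.

A tag assigned to a mature miRNA is classified by a 5'-anchored alignment
against the mature within its precursor context. 5' variation is read off
the anchor shift (3'-dominant variation is the empirical norm, so only
small shifts are searched); 3' variation splits into trimming, templated
extension (extra bases matching the precursor downstream of the mature)
and non-templated addition (extra bases that do not match, typically U or
A). Internal substitutions are recorded 1-based on the mature.

Seed edits are single-nucleotide mismatches at positions 2-8 (the seed
region) found when aligning tags that are NOT conserved assignments
against the mature set: a call requires exactly one mismatch over the
5'-anchored overlap, located in the seed.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import RNA_BASES, to_rna
from .reads import SmallRNATag
from .refs import MatureMiRNA, Precursor

__all__ = [
    "Substitution",
    "IsomiRVariant",
    "classify_isomir",
    "SeedEditCall",
    "detect_seed_edits",
    "substitution_spectrum",
    "SUBSTITUTION_TYPES",
    "edit_position_histogram",
    "SEED_POSITIONS",
]

Substitution = namedtuple("Substitution", ["position", "ref", "obs"])

SEED_POSITIONS = tuple(range(2, 9))  # 1-based positions 2..8

#: The 12 directed substitution types, in fixed reporting order.
SUBSTITUTION_TYPES: Tuple[Tuple[str, str], ...] = tuple(
    (a, b) for a in RNA_BASES for b in RNA_BASES if a != b
)

CANONICAL = "canonical"
TRIM5 = "trim5"
TRIM3 = "trim3"
EXT3_TEMPLATED = "ext3_templated"
ADD3_NONTEMPLATED = "add3_nontemplated"
SUBSTITUTION = "substitution"


@dataclass
class IsomiRVariant:
    tag: SmallRNATag
    mature_id: str
    classes: FrozenSet[str]
    added3: str = ""
    substitutions: Tuple[Substitution, ...] = ()


def classify_isomir(
    tag: SmallRNATag,
    mature: MatureMiRNA,
    precursor: Precursor,
    max_shift5: int = 4,
) -> IsomiRVariant:
    """Classify one assigned tag relative to its mature within the precursor.

    The tag is anchored at the mature 5' end; shifts of 0..``max_shift5``
    nt (5' trimming) are tried and the one maximizing agreement over the
    first bases wins, smaller shifts preferred. Raises ValueError if the
    precursor does not contain the mature.
    """
    tseq = tag.sequence
    mseq = mature.sequence
    m_start = precursor.sequence.find(mseq)
    if m_start < 0:
        raise ValueError(
            f"precursor {precursor.precursor_id} does not contain mature "
            f"{mature.mature_id}"
        )
    m_end = m_start + len(mseq)

    best_shift, best_score = 0, -1
    probe = min(10, len(tseq))
    for d in range(0, max_shift5 + 1):
        ref = mseq[d : d + probe]
        score = sum(1 for a, b in zip(tseq[: len(ref)], ref) if a == b)
        if score > best_score:
            best_shift, best_score = d, score
    d = best_shift

    classes = set()
    if d > 0:
        classes.add(TRIM5)

    # overlap with the (shifted) mature
    ref_tail = mseq[d:]
    overlap = min(len(tseq), len(ref_tail))
    subs = tuple(
        Substitution(d + i + 1, ref_tail[i], tseq[i])
        for i in range(overlap)
        if tseq[i] != ref_tail[i]
    )
    if subs:
        classes.add(SUBSTITUTION)

    added3 = ""
    if len(tseq) < len(ref_tail):
        classes.add(TRIM3)
    elif len(tseq) > len(ref_tail):
        ext = tseq[len(ref_tail) :]
        downstream = precursor.sequence[m_end : m_end + len(ext)]
        n_templated = 0
        for i, base in enumerate(ext):
            if i < len(downstream) and base == downstream[i]:
                n_templated += 1
            else:
                break
        if n_templated:
            classes.add(EXT3_TEMPLATED)
        if n_templated < len(ext):
            classes.add(ADD3_NONTEMPLATED)
            added3 = ext[n_templated:]

    if not classes:
        classes.add(CANONICAL)
    return IsomiRVariant(tag, mature.mature_id, frozenset(classes), added3, subs)


@dataclass(frozen=True)
class SeedEditCall:
    tag: SmallRNATag
    mature_id: str
    position: int  # 1-based on the mature, within 2..8
    ref: str
    obs: str

    @property
    def count_a(self) -> int:
        return self.tag.count_a

    @property
    def count_b(self) -> int:
        return self.tag.count_b


def detect_seed_edits(
    tags: Sequence[SmallRNATag],
    mature_set: Sequence,
    min_overlap: int = 16,
) -> List[SeedEditCall]:
    """Seed-edit calls from tags not assigned as conserved miRNAs.

    A call is emitted iff the 5'-anchored overlap with some mature shows
    exactly one mismatch and that mismatch sits at positions 2-8. If
    several matures qualify, the lexicographically smallest id is kept.
    """
    matures: List[MatureMiRNA] = []
    for m in mature_set:
        if isinstance(m, MatureMiRNA):
            matures.append(m)
        else:
            matures.append(MatureMiRNA(m[0], to_rna(m[1])))
    matures.sort(key=lambda m: m.mature_id)
    calls = []
    for tag in tags:
        for mat in matures:
            overlap = min(len(tag.sequence), len(mat.sequence))
            if overlap < min_overlap:
                continue
            mismatches = [
                i
                for i in range(overlap)
                if tag.sequence[i] != mat.sequence[i]
            ]
            if len(mismatches) != 1:
                continue
            pos = mismatches[0] + 1  # 1-based
            if pos in SEED_POSITIONS:
                calls.append(
                    SeedEditCall(
                        tag,
                        mat.mature_id,
                        pos,
                        mat.sequence[mismatches[0]],
                        tag.sequence[mismatches[0]],
                    )
                )
                break
    return calls


def substitution_spectrum(
    variants: Sequence[IsomiRVariant] = (),
    seed_calls: Sequence[SeedEditCall] = (),
) -> pd.DataFrame:
    """The 12-type substitution spectrum, read-count weighted.

    Pools every single-nucleotide substitution event carried by isomiR
    variants and seed-edit calls; returns per-condition and pooled counts
    and fractions (fractions sum to 1 when any events exist).
    """
    counts = {t: {"count_a": 0, "count_b": 0} for t in SUBSTITUTION_TYPES}
    for var in variants:
        for sub in var.substitutions:
            key = (sub.ref, sub.obs)
            counts[key]["count_a"] += var.tag.count_a
            counts[key]["count_b"] += var.tag.count_b
    for call in seed_calls:
        key = (call.ref, call.obs)
        counts[key]["count_a"] += call.count_a
        counts[key]["count_b"] += call.count_b
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.index = pd.Index(
        [f"{a}->{b}" for a, b in SUBSTITUTION_TYPES], name="substitution"
    )
    df["count"] = df["count_a"] + df["count_b"]
    for col in ("count_a", "count_b", "count"):
        total = df[col].sum()
        df[col.replace("count", "fraction")] = (
            df[col] / total if total > 0 else 0.0
        )
    return df


def edit_position_histogram(calls: Sequence[SeedEditCall]) -> pd.Series:
    """Number of seed-edit calls per seed position (2-8); sums to len(calls)."""
    hist = pd.Series(0, index=pd.Index(SEED_POSITIONS, name="position"))
    for call in calls:
        hist[call.position] += 1
    return hist
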