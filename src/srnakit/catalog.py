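"""Conserved miRNA identification, families, arm pairing, novel prediction.

Conserved identification matches tags 5'-anchored against a mature
reference set allowing up to two substitutions over the overlap (the tag
may run short or long at its 3' end). Families are equivalence classes of
identical seed (positions 2-8). A miRNA:miRNA* duplex pair is reported
when both arms of one precursor carry assigned expression.

Novel prediction excises genomic windows around unassigned mapped tags,
folds them, and keeps loci whose structure is a single clean hairpin with
the candidate mature inside one arm, sufficiently paired, with MFE below
a ceiling, and with homogeneous 5' read ends (Dicer-consistency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._seq import revcomp_dna, to_rna
from .annotate import GenomeHit
from .fold import extract_stem_loop, hairpin_loops, paired_positions
from .reads import SmallRNATag
from .refs import MatureMiRNA, Precursor

__all__ = [
    "MiRNARecord",
    "identify_conserved",
    "group_families",
    "pair_arms",
    "first_base_bias",
    "NovelCandidate",
    "predict_novel",
]


@dataclass
class MiRNARecord:
    mature_id: str
    sequence: str
    precursor_id: str
    arm: str
    family: str
    count_a: int = 0
    count_b: int = 0

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


def _mature_items(mature_set: Sequence) -> List[MatureMiRNA]:
    items = []
    for m in mature_set:
        if isinstance(m, MatureMiRNA):
            items.append(m)
        else:
            mid, seq = m[0], m[1]
            items.append(MatureMiRNA(mid, to_rna(seq)))
    return items


def _overlap_mismatches(tag_seq: str, mature_seq: str) -> Tuple[int, int]:
    """(mismatches, overlap) for a 5'-anchored ungapped comparison."""
    overlap = min(len(tag_seq), len(mature_seq))
    mm = sum(1 for i in range(overlap) if tag_seq[i] != mature_seq[i])
    return mm, overlap


def identify_conserved(
    tags: Sequence[SmallRNATag],
    mature_set: Sequence,
    max_mismatch: int = 2,
    min_overlap: int = 16,
) -> Tuple[List[MiRNARecord], Dict[str, str]]:
    """Assign tags to mature references with at most ``max_mismatch``
    substitutions over the 5'-anchored overlap.

    Each tag goes to at most one mature; ties are broken by (fewest
    mismatches, longest overlap, lexicographically smallest id). Returns
    per-miRNA records with summed tag counts, plus the tag-sequence ->
    mature-id assignment map.
    """
    matures = _mature_items(mature_set)
    if not matures:
        raise ValueError("mature_set must be non-empty")
    records: Dict[str, MiRNARecord] = {}
    assignments: Dict[str, str] = {}
    for tag in tags:
        best = None  # (mm, -overlap, id, mature)
        for mat in matures:
            mm, ov = _overlap_mismatches(tag.sequence, mat.sequence)
            if ov < min_overlap or mm > max_mismatch:
                continue
            key = (mm, -ov, mat.mature_id)
            if best is None or key < best[0]:
                best = (key, mat)
        if best is None:
            continue
        mat = best[1]
        assignments[tag.sequence] = mat.mature_id
        rec = records.get(mat.mature_id)
        if rec is None:
            rec = MiRNARecord(
                mat.mature_id, mat.sequence, mat.precursor_id, mat.arm,
                family=_seed(mat.sequence),
            )
            records[mat.mature_id] = rec
        rec.count_a += tag.count_a
        rec.count_b += tag.count_b
    ordered = sorted(records.values(), key=lambda r: (-r.total, r.mature_id))
    return ordered, assignments


def _seed(sequence: str) -> str:
    """Seed region, positions 2-8 (1-based) from the 5' end."""
    return sequence[1:8]


def group_families(records: Sequence) -> Dict[str, List[str]]:
    """Group matures (or records) into families by identical seed."""
    families: Dict[str, List[str]] = {}
    for rec in records:
        if isinstance(rec, MiRNARecord):
            rid, seq = rec.mature_id, rec.sequence
        elif isinstance(rec, MatureMiRNA):
            rid, seq = rec.mature_id, rec.sequence
        else:
            rid, seq = rec[0], to_rna(rec[1])
        families.setdefault(_seed(seq), []).append(rid)
    return {seed: sorted(ids) for seed, ids in families.items()}


def pair_arms(
    records: Sequence[MiRNARecord], precursor_set: Sequence[Precursor]
) -> List[Tuple[MiRNARecord, MiRNARecord]]:
    """miRNA:miRNA* duplex pairs: both arms of one precursor expressed."""
    known = {p.precursor_id for p in precursor_set}
    by_prec: Dict[str, Dict[str, MiRNARecord]] = {}
    for rec in records:
        if rec.precursor_id and rec.precursor_id in known and rec.total > 0:
            by_prec.setdefault(rec.precursor_id, {})[rec.arm] = rec
    pairs = []
    for prec_id in sorted(by_prec):
        arms = by_prec[prec_id]
        if "5p" in arms and "3p" in arms:
            pairs.append((arms["5p"], arms["3p"]))
    return pairs


def first_base_bias(
    tags: Sequence, min_len: int = 18, max_len: int = 26
) -> pd.DataFrame:
    """Per-length first-nucleotide fractions, weighted by read counts.

    Accepts tags or miRNA records; rows are lengths with any mass, columns
    A/C/G/U fractions summing to 1 per row.
    """
    counts: Dict[int, Dict[str, float]] = {}
    for item in tags:
        if isinstance(item, SmallRNATag):
            seq, weight = item.sequence, item.total
        elif isinstance(item, MiRNARecord):
            seq, weight = item.sequence, item.total
        else:
            seq, weight = to_rna(item), 1
        L = len(seq)
        if L < min_len or L > max_len or weight == 0:
            continue
        row = counts.setdefault(L, {b: 0.0 for b in "ACGU"})
        row[seq[0]] += weight
    df = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    if df.empty:
        return pd.DataFrame(columns=list("ACGU"))
    return df.div(df.sum(axis=1), axis=0)[list("ACGU")]


@dataclass
class NovelCandidate:
    mature_sequence: str
    chrom: str
    start: int  # forward-strand start of the mature hit
    strand: str
    precursor_sequence: str  # excised hairpin window, RNA, hit-strand orientation
    precursor_start: int  # forward-strand start of the window
    structure: str
    mfe: float
    star_support: bool
    n_supporting: int
    five_prime_span: int


def _cluster_hits(
    hits: Sequence[GenomeHit], max_5p_span: int
) -> List[List[GenomeHit]]:
    def five_prime(h: GenomeHit) -> int:
        return h.start if h.strand == "+" else h.end

    groups: Dict[Tuple[str, str], List[GenomeHit]] = {}
    for h in hits:
        groups.setdefault((h.chrom, h.strand), []).append(h)
    clusters = []
    for key in sorted(groups):
        members = sorted(groups[key], key=five_prime)
        current = [members[0]]
        for h in members[1:]:
            if five_prime(h) - five_prime(current[0]) <= max_5p_span:
                current.append(h)
            else:
                clusters.append(current)
                current = [h]
        clusters.append(current)
    return clusters


def predict_novel(
    hits: Sequence[GenomeHit],
    genome: Dict[str, str],
    fold_engine,
    tag_counts: Optional[Dict[str, int]] = None,
    flank_proximal: int = 20,
    flank_distal: int = 160,
    mfe_ceiling: float = -18.0,
    min_paired: int = 14,
    max_5p_span: int = 4,
) -> List[NovelCandidate]:
    """Hairpin-based novel miRNA prediction from unassigned genome hits.

    Hits are clustered by shared 5' end (within ``max_5p_span`` nt, the
    Dicer-consistency rule); for each cluster the most abundant tag is the
    candidate mature. A genomic window with ``flank_proximal`` nt on one
    side of the tag and ``flank_distal`` on the other is excised in both
    orientations and folded; the stem-loop substructure enclosing the tag
    is then cut out and re-folded, and the candidate is kept when that
    hairpin has a single terminal loop, the mature entirely within one
    arm with at least ``min_paired`` bases paired, and MFE at or below
    the ceiling. The lower-MFE passing orientation wins.
    """
    if fold_engine is None:
        raise ValueError(
            "no fold engine configured; pass get_fold_engine('vienna') or "
            "the bundled get_fold_engine('nussinov') fallback"
        )
    if isinstance(genome, str):
        genome = {"chr1": genome}
    tag_counts = tag_counts or {}
    candidates = []
    for cluster in _cluster_hits(list(hits), max_5p_span):
        rep = min(
            cluster,
            key=lambda h: (-tag_counts.get(h.tag_sequence, 1), h.tag_sequence),
        )
        chrom_seq = genome[rep.chrom]
        five_prime = [h.start if h.strand == "+" else h.end for h in cluster]
        span = max(five_prime) - min(five_prime)
        found = None
        for up, down in (
            (flank_proximal, flank_distal),
            (flank_distal, flank_proximal),
        ):
            if rep.strand == "+":
                left, right = up, down
            else:
                left, right = down, up
            ws = max(0, rep.start - left)
            we = min(len(chrom_seq), rep.end + right)
            window_dna = chrom_seq[ws:we]
            if rep.strand == "+":
                window = to_rna(window_dna)
                offset = rep.start - ws
            else:
                window = to_rna(revcomp_dna(window_dna))
                offset = we - rep.end
            L = len(rep.tag_sequence)
            structure, _ = fold_engine.fold(window)
            sub_span = extract_stem_loop(structure, offset, offset + L)
            if sub_span is None:
                continue
            sub_s, sub_e = sub_span
            hairpin = window[sub_s:sub_e]
            sub_structure, mfe = fold_engine.fold(hairpin)
            sub_offset = offset - sub_s
            ok = _hairpin_checks(sub_structure, sub_offset, L, min_paired)
            if ok and mfe <= mfe_ceiling and (found is None or mfe < found.mfe):
                # window span back on forward-strand genome coordinates
                if rep.strand == "+":
                    hp_start = ws + sub_s
                else:
                    hp_start = we - sub_e
                found = NovelCandidate(
                    mature_sequence=rep.tag_sequence,
                    chrom=rep.chrom,
                    start=rep.start,
                    strand=rep.strand,
                    precursor_sequence=hairpin,
                    precursor_start=hp_start,
                    structure=sub_structure,
                    mfe=float(mfe),
                    star_support=_star_supported(
                        cluster, hits, rep,
                        hp_start, hp_start + len(hairpin),
                        sub_structure, sub_offset,
                    ),
                    n_supporting=len(cluster),
                    five_prime_span=span,
                )
        if found:
            candidates.append(found)
    candidates.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return candidates


def _hairpin_checks(
    structure: str,
    offset: int,
    mature_len: int,
    min_paired: int,
    max_loop_overlap: int = 4,
) -> bool:
    """Single terminal loop; mature inside one arm; enough mature pairing.

    A mature spanning the terminal loop (reaching into both arms) is
    rejected; a short intrusion into the loop (up to ``max_loop_overlap``
    nt) is tolerated, since Dicer products sit flush against the loop and
    predicted loop boundaries wobble by a few bases.
    """
    loops = hairpin_loops(structure)
    if len(loops) != 1:
        return False
    loop_s, loop_e = loops[0]
    m_s, m_e = offset, offset + mature_len
    if m_s < 0 or m_e > len(structure):
        return False
    if m_s < loop_s and m_e > loop_e:  # spans the loop into both arms
        return False
    if max(0, min(m_e, loop_e) - max(m_s, loop_s)) > max_loop_overlap:
        return False
    paired = paired_positions(structure)
    return sum(1 for i in range(m_s, m_e) if i in paired) >= min_paired


def _star_supported(cluster, all_hits, rep, ws, we, structure, offset) -> bool:
    """Any other hit inside the window on the opposite side of the loop."""
    loops = hairpin_loops(structure)
    if not loops:
        return False
    loop_s, _loop_e = loops[0]
    mature_is_5p = offset + len(rep.tag_sequence) <= loop_s
    in_cluster = {id(h) for h in cluster}
    for h in all_hits:
        if id(h) in in_cluster or h.chrom != rep.chrom or h.strand != rep.strand:
            continue
        if h.start < ws or h.end > we:
            continue
        if rep.strand == "+":
            h_off = h.start - ws
        else:
            h_off = we - h.end
        h_is_5p = h_off + len(h.tag_sequence) <= loop_s
        if h_is_5p != mature_is_5p:
            return True
    return False
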