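"""Rule-based miRNA target prediction with G:U-aware mismatch accounting.

A miRNA is aligned antiparallel and ungapped against a candidate site;
each miRNA position (1-based from the 5' end) is in one of three pair
states: Watson-Crick pair, G:U wobble pair, or mismatch. G:U wobbles are
pairs for adjacency purposes but cost 0.5 mismatch units in the counting
criteria. A site passes when all six filters hold:

  c1  total mismatch units <= 4 (G:U = 0.5)
  c2  no run of more than two adjacent mismatches
  c3  no adjacent mismatches within positions 2-12
  c4  no mismatch at positions 10-11
  c5  at most 2.5 mismatch units within positions 1-12
  c6  duplex MFE at least 75% as favorable as the miRNA bound to its
      perfect complement (duplex_mfe <= 0.75 * perfect_mfe, both negative)

Duplex energies come from a configurable engine: the ViennaRNA
``duplexfold`` routine by default, or a bundled additive model (stacked
WC pair -2.0, G:U -1.0 kcal/mol, +3.0 per mismatch run) for
dependency-free, engine-pinned tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import GU_PAIRS, WC_PAIRS, revcomp_rna, to_rna

__all__ = [
    "WC_PAIR",
    "GU_PAIR",
    "MISMATCH",
    "TargetDuplex",
    "duplex_align",
    "AdditiveDuplexEnergy",
    "ViennaDuplexEnergy",
    "get_duplex_engine",
    "duplex_mfe",
    "perfect_mfe",
    "FilterReport",
    "apply_filters",
    "scan_targets",
]

WC_PAIR = "WC_pair"
GU_PAIR = "GU_pair"
MISMATCH = "mismatch"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# state codes: 0 = WC, 1 = GU, 2 = mismatch
_STATE_TABLE = np.full((4, 4), 2, dtype=np.int8)
for _a, _b in WC_PAIRS:
    _STATE_TABLE[_BASE_CODE[_a], _BASE_CODE[_b]] = 0
for _a, _b in GU_PAIRS:
    _STATE_TABLE[_BASE_CODE[_a], _BASE_CODE[_b]] = 1
_STATE_NAME = {0: WC_PAIR, 1: GU_PAIR, 2: MISMATCH}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[c] for c in seq], dtype=np.int8)


@dataclass
class TargetDuplex:
    mirna_id: str
    mirna_sequence: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    site_sequence: str
    pair_states: Tuple[str, ...]  # index 0 = miRNA position 1 (5')
    mismatch_score: float
    mfe: Optional[float] = None
    perfect_mfe: Optional[float] = None


def duplex_align(mirna: str, site: str) -> TargetDuplex:
    """Best ungapped antiparallel register of a miRNA against a site.

    miRNA position i pairs the site base ``site[S-1-i-r]`` for a register
    shift r; all shifts placing the miRNA within (or overhanging) the
    site are tried and the one maximizing WC+GU pairings wins, leftmost
    register on ties. Site length must lie within [L-5, L+10] of the
    miRNA length L. Unopposed miRNA positions count as mismatches.
    """
    mirna, site = to_rna(mirna), to_rna(site)
    if not mirna or not site:
        raise ValueError("miRNA and site must be non-empty")
    L, S = len(mirna), len(site)
    if S < L - 5 or S > L + 10:
        raise ValueError(
            f"site length {S} outside [{L - 5}, {L + 10}] for miRNA length {L}"
        )
    m = _encode(mirna)
    s = _encode(site)
    lo, hi = min(0, S - L), max(0, S - L)
    best_states, best_pairs, best_r = None, -1, None
    for r in range(lo, hi + 1):
        j = S - 1 - np.arange(L) - r
        valid = (j >= 0) & (j < S)
        states = np.full(L, 2, dtype=np.int8)
        states[valid] = _STATE_TABLE[m[valid], s[j[valid]]]
        n_pairs = int(np.sum(states < 2))
        if n_pairs > best_pairs:
            best_states, best_pairs, best_r = states, n_pairs, r
    states = best_states
    score = float(np.sum(states == 2) + 0.5 * np.sum(states == 1))
    return TargetDuplex(
        mirna_id="",
        mirna_sequence=mirna,
        transcript_id="",
        site_start=0,
        site_end=S,
        site_sequence=site,
        pair_states=tuple(_STATE_NAME[int(c)] for c in states),
        mismatch_score=score,
    )


class AdditiveDuplexEnergy:
    """Additive duplex model: WC -2.0, G:U -1.0, +3.0 per mismatch run."""

    name = "additive"

    def energy(self, mirna: str, site: str, pair_states: Sequence[str]) -> float:
        states = list(pair_states)
        if all(st == MISMATCH for st in states):
            return 0.0
        e = -2.0 * states.count(WC_PAIR) - 1.0 * states.count(GU_PAIR)
        in_run = False
        for st in states:
            if st == MISMATCH and not in_run:
                e += 3.0
                in_run = True
            elif st != MISMATCH:
                in_run = False
        return e


class ViennaDuplexEnergy:
    """ViennaRNA ``duplexfold`` hybridization energy (kcal/mol)."""

    name = "vienna"

    def __init__(self):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA python bindings are unavailable; use the bundled "
                "additive engine via get_duplex_engine('additive')"
            ) from exc
        self._rna = __import__("RNA")

    def energy(self, mirna: str, site: str, pair_states: Sequence[str]) -> float:
        return float(self._rna.duplexfold(to_rna(mirna), to_rna(site)).energy)


def get_duplex_engine(name: str = "vienna"):
    if name == "vienna":
        return ViennaDuplexEnergy()
    if name == "additive":
        return AdditiveDuplexEnergy()
    raise ValueError(f"unknown duplex energy engine: {name!r}")


def duplex_mfe(duplex: TargetDuplex, engine) -> float:
    """Energy of a duplex under the configured engine (stored on the duplex)."""
    e = engine.energy(duplex.mirna_sequence, duplex.site_sequence, duplex.pair_states)
    duplex.mfe = e
    return e


def perfect_mfe(mirna: str, engine) -> float:
    """Energy of the miRNA bound to its exact reverse complement."""
    site = revcomp_rna(to_rna(mirna))
    d = duplex_align(mirna, site)
    return engine.energy(d.mirna_sequence, d.site_sequence, d.pair_states)


@dataclass
class FilterReport:
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    values: Dict[str, float]

    @property
    def passed(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4 and self.c5 and self.c6


def apply_filters(
    duplex: TargetDuplex,
    max_mismatch_score: float = 4.0,
    max_adjacent: int = 2,
    seed_adjacent_limit: int = 12,
    central_positions: Tuple[int, int] = (10, 11),
    max_five_prime_score: float = 2.5,
    mfe_fraction: float = 0.75,
) -> FilterReport:
    """Evaluate the six target-site criteria on an aligned duplex.

    ``duplex.mfe`` and ``duplex.perfect_mfe`` must be set for c6; all
    positions are 1-based from the miRNA 5' end.
    """
    states = duplex.pair_states
    L = len(states)
    mm = [st == MISMATCH for st in states]
    gu = [st == GU_PAIR for st in states]

    score = sum(mm) + 0.5 * sum(gu)
    c1 = score <= max_mismatch_score

    longest_run = run = 0
    for flag in mm:
        run = run + 1 if flag else 0
        longest_run = max(longest_run, run)
    c2 = longest_run <= max_adjacent

    c3 = True
    for pos in range(2, seed_adjacent_limit):  # pairs (pos, pos+1), both <= limit
        if mm[pos - 1] and pos < L and mm[pos]:
            c3 = False
            break

    c4 = not any(mm[p - 1] for p in central_positions if p <= L)

    k = min(seed_adjacent_limit, L)
    score5 = sum(mm[:k]) + 0.5 * sum(gu[:k])
    c5 = score5 <= max_five_prime_score

    if duplex.mfe is None or duplex.perfect_mfe is None:
        raise ValueError("duplex energies must be computed before filtering")
    ratio = duplex.mfe / duplex.perfect_mfe if duplex.perfect_mfe != 0 else 0.0
    c6 = duplex.perfect_mfe < 0 and duplex.mfe <= mfe_fraction * duplex.perfect_mfe

    return FilterReport(
        bool(c1), bool(c2), bool(c3), bool(c4), bool(c5), bool(c6),
        values={
            "mismatch_score": float(score),
            "longest_mismatch_run": float(longest_run),
            "five_prime_score": float(score5),
            "mfe": float(duplex.mfe),
            "perfect_mfe": float(duplex.perfect_mfe),
            "mfe_ratio": float(ratio),
        },
    )


def _window_states(mirna_codes: np.ndarray, transcript_codes: np.ndarray) -> np.ndarray:
    """(n_windows, L) pair-state codes for every same-length window."""
    L = len(mirna_codes)
    windows = np.lib.stride_tricks.sliding_window_view(transcript_codes, L)
    # miRNA position i (0-based) faces window base L-1-i: reverse the window
    return _STATE_TABLE[mirna_codes[None, :], windows[:, ::-1]]


def scan_targets(
    mirna_id: str,
    mirna: str,
    transcripts: Sequence[Tuple[str, str]],
    engine=None,
    max_transcript_length: int = 100_000,
    **filter_kwargs,
) -> List[Tuple[TargetDuplex, FilterReport]]:
    """All passing target sites of one miRNA over full transcripts.

    Every same-length window (stride 1) is aligned and filtered;
    overlapping passing windows are merged keeping the lowest-MFE site
    (leftmost on ties). Sites anywhere on the transcript are eligible
    (3' UTR, coding sequence and 5' UTR alike).
    """
    engine = engine or AdditiveDuplexEnergy()
    mirna = to_rna(mirna)
    m_codes = _encode(mirna)
    L = len(mirna)
    p_mfe = perfect_mfe(mirna, engine)
    results: List[Tuple[TargetDuplex, FilterReport]] = []
    for tid, tseq in transcripts:
        tseq = to_rna(tseq)
        if len(tseq) > max_transcript_length:
            raise ValueError(
                f"transcript {tid} longer than {max_transcript_length} nt"
            )
        if len(tseq) < L:
            continue
        t_codes = _encode(tseq)
        states = _window_states(m_codes, t_codes)
        mm = states == 2
        gu = states == 1
        # vectorized prefilter on the counting criteria (c1, c2, c3, c4, c5)
        score = mm.sum(axis=1) + 0.5 * gu.sum(axis=1)
        ok = score <= filter_kwargs.get("max_mismatch_score", 4.0)
        if L >= 3:
            run3 = mm[:, :-2] & mm[:, 1:-1] & mm[:, 2:]
            ok &= ~run3.any(axis=1)
        hi = min(filter_kwargs.get("seed_adjacent_limit", 12), L)
        if hi >= 3:
            adj = mm[:, 1 : hi - 1] & mm[:, 2:hi]
            ok &= ~adj.any(axis=1)
        for p in filter_kwargs.get("central_positions", (10, 11)):
            if p <= L:
                ok &= ~mm[:, p - 1]
        k = min(filter_kwargs.get("seed_adjacent_limit", 12), L)
        ok &= (mm[:, :k].sum(axis=1) + 0.5 * gu[:, :k].sum(axis=1)) <= (
            filter_kwargs.get("max_five_prime_score", 2.5)
        )
        passing: List[Tuple[TargetDuplex, FilterReport]] = []
        for start in np.flatnonzero(ok):
            start = int(start)
            site = tseq[start : start + L]
            dup = duplex_align(mirna, site)
            dup.mirna_id = mirna_id
            dup.transcript_id = tid
            dup.site_start = start
            dup.site_end = start + L
            dup.perfect_mfe = p_mfe
            duplex_mfe(dup, engine)
            report = apply_filters(dup, **filter_kwargs)
            if report.passed:
                passing.append((dup, report))
        results.extend(_merge_overlaps(passing))
    return results


def _merge_overlaps(
    sites: List[Tuple[TargetDuplex, FilterReport]]
) -> List[Tuple[TargetDuplex, FilterReport]]:
    """Merge overlapping passing windows, keeping the lowest-MFE site."""
    if not sites:
        return []
    sites = sorted(sites, key=lambda sr: sr[0].site_start)
    merged = []
    group = [sites[0]]
    group_end = sites[0][0].site_end
    for item in sites[1:]:
        if item[0].site_start < group_end:
            group.append(item)
            group_end = max(group_end, item[0].site_end)
        else:
            merged.append(min(group, key=lambda sr: (sr[0].mfe, sr[0].site_start)))
            group = [item]
            group_end = item[0].site_end
    merged.append(min(group, key=lambda sr: (sr[0].mfe, sr[0].site_start)))
    return merged
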