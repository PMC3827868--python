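"""RNA secondary-structure engines for hairpin-precursor evaluation.

Two interchangeable engines expose ``fold(seq) -> (dot_bracket, mfe)``:

* :class:`ViennaFold` — binds the ViennaRNA python API (thermodynamic
  nearest-neighbor model); the default when the ``RNA`` module is
  importable.
* :class:`NussinovFold` — a self-contained base-pair-maximisation folder
  with simple pair energies (GC −3, AU −2, GU −1 kcal/mol, hairpin loops
  of at least 3 nt). Deterministic and dependency-free; useful for unit
  tests and environments without ViennaRNA. Its energies are NOT on the
  thermodynamic scale of ViennaRNA, so MFE ceilings must be calibrated
  per engine.

Dot-bracket utilities used by the novel-miRNA predictor (loop location,
pairedness of a subinterval) live here too.
"""

from __future__ import annotations

import re
from typing import List, Optional, Tuple

__all__ = [
    "NussinovFold",
    "ViennaFold",
    "get_fold_engine",
    "paired_positions",
    "hairpin_loops",
    "pair_table",
    "extract_stem_loop",
]

_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}


class NussinovFold:
    """Minimum-energy folding by dynamic programming over pair energies.

    Recursion: E(i,j) = min( E(i+1,j),
                             min_k { e(i,k) + E(i+1,k-1) + E(k+1,j) } )
    with pairing (i,k) allowed only when k - i > min_loop.
    Traceback prefers leaving ``i`` unpaired, then the smallest pairing
    partner, which makes the reported structure deterministic.
    """

    name = "nussinov"

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def fold(self, seq: str) -> Tuple[str, float]:
        s = seq.upper().replace("T", "U")
        n = len(s)
        if n == 0:
            return "", 0.0
        INF = float("inf")
        E = [[0.0] * n for _ in range(n)]
        for span in range(self.min_loop + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = E[i + 1][j]
                for k in range(i + self.min_loop + 1, j + 1):
                    e = _PAIR_ENERGY.get((s[i], s[k]))
                    if e is None:
                        continue
                    inner = E[i + 1][k - 1] if k - 1 > i + 1 else 0.0
                    outer = E[k + 1][j] if k + 1 <= j else 0.0
                    cand = e + inner + outer
                    if cand < best:
                        best = cand
                E[i][j] = best if best < INF else 0.0
        structure = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or j - i <= self.min_loop:
                continue
            if E[i][j] == E[i + 1][j]:
                stack.append((i + 1, j))
                continue
            for k in range(i + self.min_loop + 1, j + 1):
                e = _PAIR_ENERGY.get((s[i], s[k]))
                if e is None:
                    continue
                inner = E[i + 1][k - 1] if k - 1 > i + 1 else 0.0
                outer = E[k + 1][j] if k + 1 <= j else 0.0
                if abs(E[i][j] - (e + inner + outer)) < 1e-9:
                    structure[i] = "("
                    structure[k] = ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
        return "".join(structure), E[0][n - 1]


class ViennaFold:
    """ViennaRNA MFE folding (``RNA.fold``)."""

    name = "vienna"

    def __init__(self):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA python bindings are unavailable; use the bundled "
                "fallback engine via get_fold_engine('nussinov')"
            ) from exc
        self._rna = __import__("RNA")

    def fold(self, seq: str) -> Tuple[str, float]:
        structure, mfe = self._rna.fold(seq.upper().replace("T", "U"))
        return structure, float(mfe)


def get_fold_engine(name: str = "vienna"):
    """Factory for fold engines by name ('vienna' or 'nussinov')."""
    if name == "vienna":
        return ViennaFold()
    if name == "nussinov":
        return NussinovFold()
    raise ValueError(f"unknown fold engine: {name!r}")


def paired_positions(structure: str) -> set:
    """0-based indices that are paired in a dot-bracket string."""
    return {i for i, c in enumerate(structure) if c in "()"}


def hairpin_loops(structure: str) -> List[Tuple[int, int]]:
    """Half-open intervals of terminal (innermost) hairpin loops.

    A terminal loop is a maximal run of dots directly enclosed by a
    ``(`` ... ``)`` pair. The number of such loops distinguishes a clean
    single hairpin (exactly one) from branched structures.
    """
    return [(m.start() + 1, m.end() - 1) for m in re.finditer(r"\(\.*\)", structure)]


def pair_table(structure: str) -> List[int]:
    """Partner index per position (-1 when unpaired) of a dot-bracket string."""
    partner = [-1] * len(structure)
    stack: List[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partner[i], partner[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partner


def extract_stem_loop(
    structure: str, region_start: int, region_end: int
) -> Optional[Tuple[int, int]]:
    """Span of the stem-loop substructure belonging to a region of interest.

    Picks the terminal loop that the region's bases pair across (the loop
    separating the region from its pairing partners); when the region is
    unpaired, the nearest loop. Then walks outward through enclosing
    pairs as long as the enclosed span still contains only that loop.
    Returns a half-open span covering the stem-loop and the region, or
    None when the structure has no terminal loop.
    """
    loops = hairpin_loops(structure)
    if not loops:
        return None
    partner = pair_table(structure)

    def crossing(loop: Tuple[int, int]) -> int:
        ls, le = loop
        n = 0
        for i in range(max(0, region_start), min(len(structure), region_end)):
            j = partner[i]
            if j >= 0 and ((i < ls and j >= le) or (i >= le and j < ls)):
                n += 1
        return n

    def distance(loop: Tuple[int, int]) -> int:
        ls, le = loop
        if le <= region_start:
            return region_start - le
        if ls >= region_end:
            return ls - region_end
        return -1  # overlapping

    best = max(loops, key=crossing)
    ls, le = best if crossing(best) > 0 else min(loops, key=distance)
    i, j = ls - 1, le  # innermost enclosing pair, by construction of the loop
    while True:
        a = i - 1
        while a >= 0 and structure[a] == ".":
            a -= 1
        if a < 0 or structure[a] != "(" or partner[a] <= j:
            break
        b = partner[a]
        if any((s2, e2) != (ls, le) and s2 >= a and e2 <= b for s2, e2 in loops):
            break
        i, j = a, b
    return min(i, region_start), max(j + 1, region_end)
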