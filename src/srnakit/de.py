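"""Two-library differential expression via the Audic-Claverie exact test.

With x reads for a miRNA in library A (N1 clean reads in total) and y in
library B (N2 total), the probability of observing y given x under equal
relative abundance is the negative-binomial-shaped point mass

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! * (1 + N2/N1)^(x+y+1) )

which sums to 1 over y for fixed x. Tail sums give the test:

    C(y <= y0 | x) = sum_{y'=0..y0} p(y'|x)      (lower, inclusive)
    D(y >= y0 | x) = sum_{y'>=y0}   p(y'|x)      (upper, inclusive)

The two-sided p-value is p = min(1, 2*min( C(y<=y_obs), D(y>=y_obs+1) )).
Splitting the point mass this way makes the p-value exactly symmetric
under the swap (x, N1) <-> (y, N2), via the identity
C(y<=y0 | x0, N1, N2) = D(x>=x0+1 | y0, N2, N1); doubling both inclusive
tails would break that symmetry at small counts.

All point masses are evaluated in log-gamma space (factorials overflow
the double range near x+y ~ 170).

Expression is normalized per million clean reads; a zero count is floored
at 0.01 normalized units so fold-changes stay finite, and miRNAs below 1
normalized unit in both libraries are removed before testing. A miRNA is
called differential when |log2 fold-change| >= 1 and p < 0.05 (defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from scipy.stats import false_discovery_control

__all__ = [
    "normalize",
    "filter_low",
    "fold_change",
    "ac_point_mass",
    "ac_tail_lower",
    "ac_tail_upper",
    "exact_p",
    "DEResult",
    "call_differential",
    "ddct",
]

ZERO_EXPRESSION_FLOOR = 0.01


def normalize(count: int, total: int) -> float:
    """Per-million normalized expression with the 0.01 zero floor."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    ne = count / total * 1_000_000.0
    return ne if ne > 0 else ZERO_EXPRESSION_FLOOR


def filter_low(ne_a: float, ne_b: float) -> bool:
    """Keep a miRNA unless its normalized expression is < 1 in BOTH libraries."""
    return ne_a >= 1.0 or ne_b >= 1.0


def fold_change(ne_a: float, ne_b: float) -> float:
    """log2(NE_A / NE_B); inputs must be positive (the 0.01 floor guarantees it)."""
    if ne_a <= 0 or ne_b <= 0:
        raise ValueError("normalized expressions must be positive")
    return float(np.log2(ne_a / ne_b))


def _check_counts(x: int, y: int, n1: int, n2: int) -> None:
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be >= 1")


def _log_point_mass(y: np.ndarray, x: int, n1: int, n2: int) -> np.ndarray:
    log_r = np.log(n2) - np.log(n1)
    log1pr = np.log1p(n2 / n1)
    return (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log1pr
    )


def ac_point_mass(x: int, y: int, n1: int, n2: int) -> float:
    """p(y|x): probability of count y in B given count x in A."""
    _check_counts(x, y, n1, n2)
    return float(np.exp(_log_point_mass(np.asarray(y, dtype=float), x, n1, n2)))


def ac_tail_lower(x: int, y: int, n1: int, n2: int) -> float:
    """C(y' <= y | x): inclusive lower tail sum.

    The point masses form a negative binomial in y with x+1 successes at
    success probability N1/(N1+N2); the tail sum is evaluated through the
    regularized incomplete beta function, which is accurate to machine
    precision even for tails of length ~1e5 where direct summation
    accumulates error.
    """
    _check_counts(x, y, n1, n2)
    return float(min(1.0, betainc(x + 1, y + 1, n1 / (n1 + n2))))


def ac_tail_upper(x: int, y: int, n1: int, n2: int) -> float:
    """D(y' >= y | x): inclusive upper tail sum."""
    _check_counts(x, y, n1, n2)
    if y == 0:
        return 1.0
    return float(max(0.0, 1.0 - ac_tail_lower(x, y - 1, n1, n2)))


def exact_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value, symmetric under (x,N1) <-> (y,N2)."""
    _check_counts(x, y, n1, n2)
    lower = ac_tail_lower(x, y, n1, n2)
    upper_strict = max(0.0, 1.0 - lower)
    return min(1.0, 2.0 * min(lower, upper_strict))


@dataclass
class DEResult:
    mirna_id: str
    x: int
    y: int
    ne_a: float
    ne_b: float
    log2fc: float
    p: float
    significant: bool
    direction: str  # up_in_A | up_in_B | none


def call_differential(
    table: Union[pd.DataFrame, Iterable[Tuple[str, int, int]]],
    n1: int,
    n2: int,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full normalize -> filter -> fold-change -> exact-test chain.

    ``table`` is a DataFrame with columns (id, x, y) or an iterable of
    (id, x, y) triples; ``n1``/``n2`` are total clean reads per library.
    Returns a DataFrame sorted by p ascending (ties: |log2fc| descending,
    then id) with a supplementary Benjamini-Hochberg ``q`` column; the
    primary significance call is uncorrected, as defined above.
    """
    if isinstance(table, pd.DataFrame):
        rows = list(table[["id", "x", "y"]].itertuples(index=False, name=None))
    else:
        rows = [tuple(r) for r in table]
    results = []
    for mirna_id, x, y in rows:
        x, y = int(x), int(y)
        ne_a = normalize(x, n1)
        ne_b = normalize(y, n2)
        if not filter_low(ne_a, ne_b):
            continue
        lfc = fold_change(ne_a, ne_b)
        p = exact_p(x, y, n1, n2)
        sig = abs(lfc) >= fc_threshold and p < alpha
        direction = "none"
        if sig:
            direction = "up_in_A" if lfc > 0 else "up_in_B"
        results.append(
            DEResult(str(mirna_id), x, y, ne_a, ne_b, lfc, p, sig, direction)
        )
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return pd.DataFrame(
            columns=[
                "mirna_id", "x", "y", "ne_a", "ne_b",
                "log2fc", "p", "q", "significant", "direction",
            ]
        )
    df["q"] = false_discovery_control(df["p"], method="bh")
    df["_abs"] = df["log2fc"].abs()
    df = df.sort_values(
        ["p", "_abs", "mirna_id"], ascending=[True, False, True]
    ).drop(columns="_abs")
    return df.reset_index(drop=True)[
        ["mirna_id", "x", "y", "ne_a", "ne_b", "log2fc", "p", "q",
         "significant", "direction"]
    ]


def ddct(ct_mirna: float, ct_ref: float, calibrator_dct: float = 0.0) -> float:
    """Relative expression by the 2^-ddCt method with a reference gene.

    dCt = Ct(miRNA) - Ct(reference); ddCt = dCt - calibrator dCt.
    """
    return float(2.0 ** -((ct_mirna - ct_ref) - calibrator_dct))
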