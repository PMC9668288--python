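"""Exact 2x2 contingency-table statistics.

The two-sided p-value follows the conventional exact definition: the sum of
the probabilities, under the hypergeometric null with fixed margins, of all
tables whose probability does not exceed that of the observed table.

For small tables the computation is done in exact integer arithmetic (the
hypergeometric probabilities share a common denominator, so tie comparisons
are exact); large tables fall back to :func:`scipy.stats.fisher_exact`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

#: largest support size enumerated exactly; beyond this scipy's C path is used
ENUMERATION_CAP = 256

_Z95 = float(stats.norm.ppf(0.975))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table ``[[a, b], [c, d]]``.

    Parameters
    ----------
    a, b, c, d
        Nonnegative cell counts. Rows are the two comparison groups
        (e.g. cases / controls), columns the two outcomes (e.g. carrier /
        noncarrier).

    Returns
    -------
    float
        p in (0, 1].
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell count in table {cells}")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        # degenerate margin: only one table is possible
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    if hi - lo + 1 > ENUMERATION_CAP:
        return float(stats.fisher_exact([[a, b], [c, d]])[1])
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    acc = sum(v for v in nums if v <= obs)
    p = float(Fraction(acc, math.comb(n, c1)))
    return min(p, 1.0)


@dataclass(frozen=True)
class OddsRatio:
    """Point estimate and Woolf (log-OR normal) confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 added to every cell
    defined: bool = True


def odds_ratio_woolf(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> OddsRatio:
    """OR = (a*d)/(b*c) with a Woolf log-scale CI.

    When any cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) before computing both the estimate and the CI.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell count in table {cells}")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return OddsRatio(math.nan, math.nan, math.nan, False, defined=False)
    corrected = any(x == 0 for x in cells)
    fa, fb, fc, fd = (x + 0.5 for x in cells) if corrected else map(float, cells)
    est = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    z = float(stats.norm.ppf(1 - alpha / 2))
    log_est = math.log(est)
    return OddsRatio(
        estimate=est,
        ci_low=math.exp(log_est - z * se),
        ci_high=math.exp(log_est + z * se),
        corrected=corrected,
    )


def odds_ratio_from_frequencies(f_case: float, f_ctrl: float) -> float:
    """OR implied by carrier frequencies: (f1/(1-f1)) / (f0/(1-f0))."""
    for f in (f_case, f_ctrl):
        if not 0.0 < f < 1.0:
            raise ValueError(f"frequency {f} outside (0, 1)")
    return (f_case / (1.0 - f_case)) / (f_ctrl / (1.0 - f_ctrl))


def frequency_percent(count: int, n: int, ndigits: int | None = None) -> float:
    """Carrier count expressed as a percentage of ``n``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if count < 0 or count > n:
        raise ValueError(f"count {count} outside [0, {n}]")
    pct = 100.0 * count / n
    return round(pct, ndigits) if ndigits is not None else pct


def se_from_ci(ci_low: float, ci_high: float, alpha: float = 0.05) -> float:
    """Back-derive a log-scale SE from a printed ratio CI: (ln U - ln L)/(2 z)."""
    if not (0 < ci_low <= ci_high):
        raise ValueError("require 0 < ci_low <= ci_high")
    z = float(stats.norm.ppf(1 - alpha / 2))
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


def wald_ci(estimate: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    z = float(stats.norm.ppf(1 - alpha / 2))
    return estimate - z * se, estimate + z * se


def binomial_interval(p0: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation interval for an empirical proportion around p0."""
    half = float(stats.norm.ppf(1 - alpha / 2)) * math.sqrt(p0 * (1 - p0) / n)
    return p0 - half, p0 + half


__all__ = [
    "ENUMERATION_CAP",
    "OddsRatio",
    "binomial_interval",
    "fisher_exact_2x2",
    "frequency_percent",
    "odds_ratio_from_frequencies",
    "odds_ratio_woolf",
    "se_from_ci",
    "wald_ci",
]
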