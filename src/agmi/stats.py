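"""Hand-rolled statistical tests used by the discordance analysis.

Two tests are implemented explicitly rather than delegated, because their
internal quantities (the Kruskal-Wallis tie-correction factor, the Meng
z-test's capped ``f`` term) are part of the reported results:

* Kruskal-Wallis H with mid-rank ties and the standard tie correction,
  referred to a chi-square null with ``k - 1`` degrees of freedom.
* The Meng-Rosenthal-Rubin z-test comparing two dependent Pearson
  correlations that share one variable (here: observed HbA1c against GMI and
  against adjusted GMI on the same sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    p: float
    group_sizes: tuple[int, ...]
    tie_correction: float


@dataclass(frozen=True)
class MengTestResult:
    z: float
    p: float
    r1: float
    r2: float
    r12: float
    n: int
    f: float
    h: float


def kruskal_wallis(groups) -> KruskalWallisResult:
    """Kruskal-Wallis H test across two or more samples.

    ``H = 12/(N(N+1)) * sum n_g * Rbar_g^2 - 3(N+1)`` on mid-ranks, divided
    by the tie correction ``1 - sum(t^3 - t)/(N^3 - N)``; the p-value comes
    from chi-square with ``len(groups) - 1`` degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis groups must be non-empty")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    pos = 0
    sizes = []
    for g in groups:
        r = ranks[pos:pos + len(g)]
        pos += len(g)
        sizes.append(len(g))
        h += len(g) * r.mean() ** 2
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts ** 3 - counts).sum()) / (n_total ** 3 - n_total))
    if tie == 0.0:  # every value identical
        return KruskalWallisResult(0.0, 1.0, tuple(sizes), 0.0)
    h /= tie
    h = max(h, 0.0)  # guard tiny negative rounding
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return KruskalWallisResult(float(h), p, tuple(sizes), tie)


def meng_test(r1: float, r2: float, r12: float, n: int) -> MengTestResult:
    """Compare two dependent correlations sharing one variable.

    ``r1`` and ``r2`` correlate the shared outcome with each of two
    predictors whose mutual correlation is ``r12``; ``n`` is the common
    sample size. The statistic Fisher-transforms both correlations and
    scales their difference by a dependence factor built from
    ``f = min(1, (1 - r12) / (2 (1 - rbar^2)))`` and
    ``h = (1 - f rbar^2) / (1 - rbar^2)`` where ``rbar^2 = (r1^2 + r2^2)/2``.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("meng_test requires n > 3")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1 ** 2 + r2 ** 2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return MengTestResult(float(z), p, r1, r2, r12, int(n), float(f), float(h))
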