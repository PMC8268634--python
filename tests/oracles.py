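"""Independent brute-force oracles used to validate the statistics module.

Everything here is written from first principles — combinatorics via
``math.comb``, explicit enumeration of sample spaces, and direct dense-grid
maximisation of the nuisance likelihood without the margin factorisation or
refinement passes the implementation uses — so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import numpy as np

#: same tie conventions as the implementation (a convention, not algebra)
PMF_TIE_REL = 1e-7
STAT_TIE_ABS = 1e-12


# ---------------------------------------------------------------------------
# ordering statistic from scratch
# ---------------------------------------------------------------------------

def hypergeom_pmf(x: int, n: int, r1: int, k: int) -> float:
    """P(X = x) for X ~ Hypergeometric(n, r1, k), via binomial coefficients."""
    if x < max(0, k - (n - r1)) or x > min(r1, k):
        return 0.0
    return comb(r1, x) * comb(n - r1, k - x) / comb(n, k)


def fisher_p(a: int, b: int, c: int, d: int, alternative: str) -> float:
    n = a + b + c + d
    r1 = a + b
    k = a + c
    lo = max(0, k - (n - r1))
    hi = min(r1, k)
    pm = {x: hypergeom_pmf(x, n, r1, k) for x in range(lo, hi + 1)}
    if alternative == "less":
        return sum(p for x, p in pm.items() if x <= a)
    if alternative == "greater":
        return sum(p for x, p in pm.items() if x >= a)
    p_obs = pm[a]
    return sum(p for p in pm.values() if p <= p_obs * (1.0 + PMF_TIE_REL))


# ---------------------------------------------------------------------------
# brute-force unconditional test
# ---------------------------------------------------------------------------

def _region_multinomial(obs, alternative):
    a, b, c, d = obs
    n = a + b + c + d
    s_obs = fisher_p(a, b, c, d, alternative)
    region = []
    for aa in range(n + 1):
        for bb in range(n - aa + 1):
            for cc in range(n - aa - bb + 1):
                dd = n - aa - bb - cc
                if fisher_p(aa, bb, cc, dd, alternative) <= s_obs + STAT_TIE_ABS:
                    region.append((aa, bb, cc, dd))
    return tuple(region)


def _region_binomial(obs, alternative):
    a, b, c, d = obs
    r1, r2 = a + b, c + d
    s_obs = fisher_p(a, b, c, d, alternative)
    region = []
    for aa in range(r1 + 1):
        for cc in range(r2 + 1):
            if fisher_p(aa, r1 - aa, cc, r2 - cc, alternative) <= s_obs + STAT_TIE_ABS:
                region.append((aa, r1 - aa, cc, r2 - cc))
    return tuple(region)


def _multinom_coef(a, b, c, d):
    n = a + b + c + d
    return comb(n, a) * comb(n - a, b) * comb(n - a - b, c)


@lru_cache(maxsize=None)
def _sup_multinomial_cached(region: tuple, n: int, npts: int) -> float:
    grid = np.linspace(0.0, 1.0, npts + 2)[1:-1]
    total = np.zeros((npts, npts))
    for (a, b, c, d) in region:
        coef = _multinom_coef(a, b, c, d)
        r = a + b
        k = a + c
        u = grid**r * (1.0 - grid) ** (n - r)
        v = grid**k * (1.0 - grid) ** (n - k)
        total += coef * np.outer(u, v)
    return float(total.max())


@lru_cache(maxsize=None)
def _sup_binomial_cached(region: tuple, r1: int, r2: int, npts: int) -> float:
    grid = np.linspace(0.0, 1.0, npts + 2)[1:-1]
    total = np.zeros(npts)
    for (a, b, c, d) in region:
        coef = comb(r1, a) * comb(r2, c)
        k = a + c
        total += coef * grid**k * (1.0 - grid) ** (r1 + r2 - k)
    return float(total.max())


def boschloo_bruteforce(
    obs,
    model: str = "multinomial",
    alternative: str = "two-sided",
    npts_multinomial: int = 501,
    npts_binomial: int = 10_000,
) -> float:
    """Brute-force unconditional p: explicit enumeration + dense nuisance grid."""
    a, b, c, d = obs
    if model == "multinomial":
        region = _region_multinomial(obs, alternative)
        return min(_sup_multinomial_cached(region, a + b + c + d, npts_multinomial), 1.0)
    region = _region_binomial(obs, alternative)
    return min(_sup_binomial_cached(region, a + b, c + d, npts_binomial), 1.0)


def all_tables_with_total(n: int, nondegenerate: bool = True):
    """Every 2x2 table summing to n (optionally only those with all margins > 0)."""
    out = []
    for a in range(n + 1):
        for b in range(n - a + 1):
            for c in range(n - a - b + 1):
                d = n - a - b - c
                if nondegenerate and (
                    a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0
                ):
                    continue
                out.append((a, b, c, d))
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney enumeration oracle
# ---------------------------------------------------------------------------

def mannwhitney_exact_bruteforce(x, y) -> float:
    """Two-sided exact Mann-Whitney p by direct count over group assignments.

    The statistic is the number of (x_i, y_j) pairs won by x, with ties worth
    1/2; extremeness is measured by distance from the null centre n1*n2/2.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)

    def u_of(indices):
        grp1 = [pooled[i] for i in indices]
        grp2 = [pooled[i] for i in range(n) if i not in indices]
        u = 0.0
        for xi in grp1:
            for yj in grp2:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    centre = n1 * (n - n1) / 2.0
    dev_obs = abs(u_of(tuple(range(n1))) - centre)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(set(idx)) - centre) >= dev_obs - 1e-12:
            hits += 1
    return hits / total
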