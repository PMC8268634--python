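"""Cohort-level statistics for CTC studies.

The centerpiece is an unconditional (Barnard-type) exact test for 2x2
contingency tables ordered by Boschloo's statistic, i.e. the Fisher exact
p-value of each candidate table.  Unlike Fisher's conditional test, the
unconditional test does not condition on the observed margins: the p-value is
the supremum, over the unknown nuisance success probabilities, of the total
null probability of all tables at least as extreme as the observed one.  Two
sampling models are supported:

``binomial``
    Row totals fixed (two independent binomials), one nuisance parameter
    ``pi`` — the common column-1 probability under H0.

``multinomial``
    Only the grand total ``N`` fixed; under row/column independence the cell
    probabilities factor through two nuisance parameters ``(pi_row, pi_col)``.

The ordering statistic is the one-sided Fisher exact p for one-sided
alternatives, and the two-sided Fisher exact p computed by the
minimum-likelihood method (sum of conditional table probabilities no larger
than the observed one) for the two-sided alternative.  The minimum-likelihood
ordering is invariant under simultaneous row and column swaps, so symmetric
tables such as [[3,5],[4,2]] and [[2,4],[5,3]] receive identical two-sided
p-values.

Also provided: reconstruction of 2x2 tables from published group sizes and
percentages, Pearson marker correlation, an exact small-sample Mann-Whitney
comparison, and Kaplan-Meier / log-rank survival comparison via lifelines.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom, mannwhitneyu, pearsonr, rankdata

__all__ = [
    "ContingencyTable2x2",
    "ExactTestResult",
    "DegenerateTableError",
    "boschloo_unconditional",
    "fisher_statistic",
    "reconstruct_table",
    "pearson_marker_correlation",
    "compare_counts_mannwhitney",
    "km_logrank",
    "SurvivalComparison",
    "covariate_exact_tests",
]

Alternative = Literal["less", "greater", "two-sided"]
Model = Literal["binomial", "multinomial"]

#: relative tolerance for probability-mass ties in the minimum-likelihood
#: two-sided Fisher p (same convention as R's fisher.test)
_PMF_TIE_REL = 1e-7
#: absolute tolerance for statistic ties when building the rejection region
_STAT_TIE_ABS = 1e-12


class DegenerateTableError(ValueError):
    """Raised when a 2x2 table has a zero margin and the test is undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Integer counts [[a, b], [c, d]].

    Rows are covariate groups; columns are outcome states (here: CTC-negative,
    CTC-positive).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @classmethod
    def from_flat(cls, cells: Sequence[int]) -> "ContingencyTable2x2":
        a, b, c, d = cells
        return cls(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class ExactTestResult:
    """Outcome of the unconditional exact test."""

    p_value: float
    statistic_observed: float
    model: Model
    alternative: Alternative
    grid_resolution: int
    nuisance_argmax: tuple[float, ...]
    table: ContingencyTable2x2


# ---------------------------------------------------------------------------
# ordering statistic
# ---------------------------------------------------------------------------

def fisher_statistic(a: int, b: int, c: int, d: int, alternative: Alternative) -> float:
    """Fisher exact p of one table, used as the Boschloo ordering statistic.

    One-sided alternatives refer to the top-left cell: ``less`` is
    P(X <= a), ``greater`` is P(X >= a), with X hypergeometric given the
    table's margins.  ``two-sided`` uses the minimum-likelihood method: the
    sum of conditional probabilities of all tables (same margins) whose
    probability does not exceed the observed table's.
    """
    n = a + b + c + d
    r1 = a + b
    k = a + c
    if alternative == "less":
        return float(hypergeom.cdf(a, n, r1, k))
    if alternative == "greater":
        return float(hypergeom.sf(a - 1, n, r1, k))
    lo = max(0, k - (n - r1))
    hi = min(r1, k)
    xs = np.arange(lo, hi + 1)
    pm = hypergeom.pmf(xs, n, r1, k)
    p_obs = pm[xs == a][0]
    return float(pm[pm <= p_obs * (1.0 + _PMF_TIE_REL)].sum())


# ---------------------------------------------------------------------------
# sample spaces
# ---------------------------------------------------------------------------

def _multinomial_tables(n: int) -> np.ndarray:
    """All 2x2 tables (a, b, c, d) with a+b+c+d = n."""
    out = [
        (a, b, c, n - a - b - c)
        for a in range(n + 1)
        for b in range(n - a + 1)
        for c in range(n - a - b + 1)
    ]
    return np.asarray(out, dtype=int)


def _binomial_tables(r1: int, r2: int) -> np.ndarray:
    """All 2x2 tables with fixed row margins (r1, r2)."""
    out = [(a, r1 - a, c, r2 - c) for a in range(r1 + 1) for c in range(r2 + 1)]
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# nuisance-parameter suprema
# ---------------------------------------------------------------------------

def _open_grid(resolution: int) -> np.ndarray:
    """Uniform grid on the open interval (0, 1)."""
    return np.linspace(0.0, 1.0, resolution + 2)[1:-1]


def _bernstein(grid: np.ndarray, n: int) -> np.ndarray:
    """Matrix g**e * (1-g)**(n-e) for e = 0..n, one row per grid point."""
    e = np.arange(n + 1)[None, :]
    g = grid[:, None]
    return g**e * (1.0 - g) ** (n - e)


def _sup_multinomial(
    region: np.ndarray, n: int, grid_r: np.ndarray, grid_c: np.ndarray
) -> tuple[float, float, float]:
    """sup over (pi_row, pi_col) of the region's multinomial probability.

    The probability of a table factorises through its row and column margins,
    so the region mass collapses to a weight matrix W indexed by margins and
    the grid evaluation is a bilinear form U @ W @ V.T.
    """
    coef = np.exp(gammaln(n + 1) - gammaln(region + 1).sum(axis=1))
    r = region[:, 0] + region[:, 1]
    k = region[:, 0] + region[:, 2]
    W = np.zeros((n + 1, n + 1))
    np.add.at(W, (r, k), coef)
    M = _bernstein(grid_r, n) @ W @ _bernstein(grid_c, n).T
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    return float(M[i, j]), float(grid_r[i]), float(grid_c[j])


def _sup_binomial(
    region: np.ndarray, r1: int, r2: int, grid: np.ndarray
) -> tuple[float, float]:
    """sup over pi of the region's two-independent-binomials probability."""
    n = r1 + r2
    from scipy.special import comb

    w = np.zeros(n + 1)
    coef = comb(r1, region[:, 0]) * comb(r2, region[:, 2])
    np.add.at(w, region[:, 0] + region[:, 2], coef)
    vals = _bernstein(grid, n) @ w
    i = int(np.argmax(vals))
    return float(vals[i]), float(grid[i])


def _refined_window(center: float, step: float, resolution: int) -> np.ndarray:
    lo = max(center - step, 1e-12)
    hi = min(center + step, 1.0 - 1e-12)
    return np.linspace(lo, hi, resolution)


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

def boschloo_unconditional(
    table: ContingencyTable2x2 | Sequence[Sequence[int]] | Sequence[int],
    model: Model = "multinomial",
    alternative: Alternative = "two-sided",
    grid_resolution: int = 1001,
    refine: bool = True,
) -> ExactTestResult:
    """Unconditional exact test of association in a 2x2 table.

    Parameters
    ----------
    table
        ``ContingencyTable2x2``, nested ``[[a, b], [c, d]]``, or flat
        ``(a, b, c, d)``.
    model
        ``"multinomial"`` fixes only N (two nuisance parameters);
        ``"binomial"`` fixes the row margins (one nuisance parameter).
    alternative
        ``"two-sided"`` (default), ``"less"`` or ``"greater"`` on the
        top-left cell.
    grid_resolution
        Number of nuisance grid points per dimension on the open interval
        (0, 1); must be >= 100.  A refinement pass of the same resolution is
        run in a one-grid-step window around the argmax unless ``refine`` is
        False.

    Returns
    -------
    ExactTestResult
        With the supremum p-value, the observed ordering statistic (the
        Fisher p of the observed table) and the nuisance argmax.
    """
    tab = _coerce_table(table)
    if grid_resolution < 100:
        raise ValueError("grid_resolution must be >= 100")
    r1, r2 = tab.row_margins
    k1, k2 = tab.col_margins
    for name, margin in (("row 1", r1), ("row 2", r2), ("column 1", k1), ("column 2", k2)):
        if margin == 0:
            raise DegenerateTableError(
                f"{name} margin of the observed table is zero; the ordering "
                "statistic is undefined"
            )

    s_obs = fisher_statistic(tab.a, tab.b, tab.c, tab.d, alternative)
    if model == "multinomial":
        space = _multinomial_tables(tab.n)
    elif model == "binomial":
        space = _binomial_tables(r1, r2)
    else:
        raise ValueError(f"unknown model {model!r}")
    stats = np.array([fisher_statistic(*t, alternative) for t in space])
    region = space[stats <= s_obs + _STAT_TIE_ABS]

    grid = _open_grid(grid_resolution)
    step = grid[1] - grid[0]
    if model == "multinomial":
        p, gr, gc = _sup_multinomial(region, tab.n, grid, grid)
        if refine:
            p2, gr2, gc2 = _sup_multinomial(
                region,
                tab.n,
                _refined_window(gr, step, grid_resolution),
                _refined_window(gc, step, grid_resolution),
            )
            if p2 > p:
                p, gr, gc = p2, gr2, gc2
        argmax: tuple[float, ...] = (gr, gc)
    else:
        p, g = _sup_binomial(region, r1, r2, grid)
        if refine:
            p2, g2 = _sup_binomial(region, r1, r2, _refined_window(g, step, grid_resolution))
            if p2 > p:
                p, g = p2, g2
        argmax = (g,)

    return ExactTestResult(
        p_value=min(float(p), 1.0),
        statistic_observed=s_obs,
        model=model,
        alternative=alternative,
        grid_resolution=grid_resolution,
        nuisance_argmax=argmax,
        table=tab,
    )


def _coerce_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table, dtype=int)
    if arr.shape == (2, 2):
        return ContingencyTable2x2(*arr.ravel().tolist())
    if arr.shape == (4,):
        return ContingencyTable2x2(*arr.tolist())
    raise ValueError(f"cannot interpret {table!r} as a 2x2 table")


# ---------------------------------------------------------------------------
# table reconstruction from published percentages
# ---------------------------------------------------------------------------

def reconstruct_table(
    group_n: int,
    pct_negative: float,
    cohort_totals: tuple[int, int, int],
    tol: float = 0.05,
) -> ContingencyTable2x2:
    """Rebuild a 2x2 table from a published group size and percentage.

    Publications often report, per covariate group, only the group size and
    the percentage of outcome-negative members, plus cohort-level outcome
    totals.  Row 1 is the stated group; row 2 is its complement obtained by
    subtracting row 1 from the cohort totals ``(total_negative,
    total_positive, N)``.

    Raises
    ------
    ValueError
        If ``pct_negative * group_n / 100`` is farther than ``tol`` from an
        integer (the published percentage cannot come from integer counts),
        or if the complement row would contain a negative count.
    """
    total_neg, total_pos, big_n = cohort_totals
    if group_n > big_n:
        raise ValueError(f"group_n={group_n} exceeds cohort N={big_n}")
    if total_neg + total_pos != big_n:
        raise ValueError("cohort totals must sum to N")
    raw = pct_negative * group_n / 100.0
    a = round(raw)
    if abs(raw - a) > tol:
        raise ValueError(
            f"{pct_negative}% of n={group_n} is {raw:.4f}, which is "
            f"{abs(raw - a):.4f} away from an integer (tolerance {tol})"
        )
    b = group_n - a
    c = total_neg - a
    d = total_pos - b
    if c < 0 or d < 0:
        raise ValueError(
            f"complement row ({c}, {d}) has a negative count; group counts "
            "exceed the cohort totals"
        )
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


# ---------------------------------------------------------------------------
# marker correlation
# ---------------------------------------------------------------------------

def pearson_marker_correlation(
    cells: pd.DataFrame,
    marker_x: str = "mean_CD74",
    marker_y: str = "mean_CD44",
    ctc_only: bool = True,
) -> float:
    """Pearson correlation of two per-cell marker mean grey values.

    Restricted to CTCs (``is_ctc`` column) when ``ctc_only`` and the column is
    present.  Requires at least 3 cells and non-zero variance in both markers.
    """
    df = cells
    if ctc_only and "is_ctc" in df.columns:
        df = df[df["is_ctc"].astype(bool)]
    x = df[marker_x].to_numpy(dtype=float)
    y = df[marker_y].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 cells to correlate, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        which = marker_x if np.std(x) == 0 else marker_y
        raise ValueError(f"zero variance in {which}; correlation undefined")
    return float(pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Mann-Whitney comparison of CTC counts
# ---------------------------------------------------------------------------

def compare_counts_mannwhitney(
    group1: Sequence[float], group2: Sequence[float], exact_max_n: int = 20
) -> float:
    """Two-sided Mann-Whitney p comparing two samples of counts.

    For combined n <= ``exact_max_n`` the p-value comes from full enumeration
    of all rank assignments (valid under ties, using midranks); otherwise the
    tie-corrected normal approximation is used.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    if n1 + n2 <= exact_max_n:
        ranks = rankdata(np.concatenate([x, y]))
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        center = n1 * n2 / 2.0
        dev_obs = abs(u_obs - center)
        total = 0
        hits = 0
        base = ranks.sum()
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        return hits / total
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves per CTC stratum plus the log-rank comparison."""

    p_value: float
    test_statistic: float
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)


def km_logrank(
    records: pd.DataFrame,
    time_col: str = "survival_months",
    event_col: str = "event",
    group_col: str = "group",
) -> SurvivalComparison:
    """Product-limit survival estimates per group and the two-group log-rank p.

    ``records`` needs one row per patient with a positive time, a boolean
    event indicator (True = death observed) and a two-level group label
    (e.g. CTC-negative vs CTC-positive under a chosen cut-off).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if (records[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    groups = sorted(records[group_col].unique())
    if len(groups) < 2:
        raise ValueError(f"need two strata for a log-rank comparison, got {groups}")
    if len(groups) > 2:
        raise ValueError(f"only two-group comparison supported, got {groups}")
    if not records[event_col].astype(bool).any():
        raise ValueError("need at least one event overall")

    masks = {g: records[group_col] == g for g in groups}
    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        kmf = KaplanMeierFitter()
        sub = records[masks[g]]
        kmf.fit(sub[time_col], event_observed=sub[event_col].astype(bool), label=str(g))
        curves[str(g)] = kmf.survival_function_.rename(columns={str(g): "survival"})
    a, b = groups
    lr = logrank_test(
        records.loc[masks[a], time_col],
        records.loc[masks[b], time_col],
        event_observed_A=records.loc[masks[a], event_col].astype(bool),
        event_observed_B=records.loc[masks[b], event_col].astype(bool),
    )
    return SurvivalComparison(
        p_value=float(lr.p_value),
        test_statistic=float(lr.test_statistic),
        curves=curves,
        group_sizes={str(g): int(masks[g].sum()) for g in groups},
    )


# ---------------------------------------------------------------------------
# cohort-table driver
# ---------------------------------------------------------------------------

def covariate_exact_tests(
    patients: pd.DataFrame,
    covariates: Sequence[str],
    status_col: str = "ctc_positive_ge1",
    model: Model = "multinomial",
    grid_resolution: int = 1001,
) -> pd.DataFrame:
    """Unconditional exact test of each boolean covariate against CTC status.

    Builds, per covariate, the 2x2 table (rows covariate False/True, columns
    CTC-negative/-positive over patients with non-missing covariate) and runs
    the two-sided test.  Degenerate tables yield NaN p with a note.
    """
    rows = []
    for cov in covariates:
        sub = patients.dropna(subset=[cov])
        g = sub[cov].astype(bool)
        pos = sub[status_col].astype(bool)
        a = int(((~g) & (~pos)).sum())
        b = int(((~g) & pos).sum())
        c = int((g & (~pos)).sum())
        d = int((g & pos).sum())
        entry = {"covariate": cov, "a": a, "b": b, "c": c, "d": d, "n": a + b + c + d}
        try:
            res = boschloo_unconditional(
                (a, b, c, d), model=model, grid_resolution=grid_resolution
            )
            entry["p_value"] = res.p_value
            entry["note"] = ""
        except (DegenerateTableError, ValueError) as exc:
            entry["p_value"] = math.nan
            entry["note"] = str(exc)
        rows.append(entry)
    return pd.DataFrame(rows)
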