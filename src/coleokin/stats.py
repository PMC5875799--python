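"""Statistical layer: exact contingency tests, rank tests, kymograph correlation.

Implements the treatment-comparison toolkit used for coleoptile cohorts:

* Fisher's exact test on 2x2 tables (predicted vs observed overshoot),
  reporting the sample (cross-product) odds ratio and both the
  right-tailed and two-sided hypergeometric p-values;
* Mann-Whitney U comparisons (exact permutation null for small samples,
  tie-corrected normal approximation with continuity correction
  otherwise) for periods, pulse velocities and temporal averages;
* Pearson image correlation r between two kymographs over their jointly
  supported cells (the elongation-rate vs curvature-rate coupling
  statistic);
* a cohort comparison assembling per-plant summaries into
  straight-vs-tilted tests.

No multiple-testing correction is applied; each comparison is reported
raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ContingencyResult",
    "GroupComparison",
    "CorrelationResult",
    "fisher_exact",
    "mann_whitney_u",
    "kymograph_correlation",
    "cohort_compare",
]


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2 ints
    odds_ratio: float  # sample (cross-product) ratio
    p_right: float
    p_left: float
    p_two_sided: float
    odds_ratio_ci_wald: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return int(self.table.sum())


@dataclass
class GroupComparison:
    quantity: str
    U: float
    p_value: float
    median_x: float
    median_y: float
    n_x: int
    n_y: int
    method: str = "exact"


@dataclass
class CorrelationResult:
    r: float
    n_cells: int


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact(table, tail: str = "two_sided",
                 wald_ci: bool = False) -> ContingencyResult:
    """Fisher's exact test on a 2x2 table of non-negative integers.

    All three tail probabilities are computed (the ``tail`` argument
    selects which one populates nothing extra; every result carries
    p_right, p_left and p_two_sided).  The two-sided p sums the point
    probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (ties
    included).  The odds ratio is the sample cross-product ratio, with an
    optional Wald 95% interval — note the Wald construction is only an
    approximation and a poor one for sparse tables.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    if tail not in ("right", "left", "two_sided"):
        raise ValueError("tail must be right, left or two_sided")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        raise ValueError("both margins must be positive")
    # condition on the margins: a ~ hypergeometric(N, a+b, a+c)
    N, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = scipy.stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = pmf[a - lo]
    p_right = pmf[support >= a].sum()
    p_left = pmf[support <= a].sum()
    # two-sided: all tables at most as probable as the observed one
    # (ties included, with a relative tolerance against roundoff)
    p_two = pmf[pmf <= p_obs * (1 + 1e-10)].sum()
    odds = _sample_odds_ratio(a, b, c, d)
    ci = None
    if wald_ci and np.isfinite(odds) and min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci = (odds * math.exp(-1.96 * se), odds * math.exp(1.96 * se))
    return ContingencyResult(t, odds, float(p_right), float(p_left),
                             float(p_two), ci)


def conditional_mle_odds_ratio(table) -> float:
    """Conditional maximum-likelihood odds ratio (noncentral hypergeometric)."""
    res = scipy.stats.contingency.odds_ratio(np.asarray(table, dtype=int),
                                             kind="conditional")
    return float(res.statistic)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample via midrank sums."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2)


def _exact_perm_p(x: np.ndarray, y: np.ndarray, U_obs: float) -> float:
    """Two-sided exact permutation p by full enumeration (handles ties)."""
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    dev_obs = abs(U_obs - mu)
    total = math.comb(n1 + n2, n1)
    count = 0
    for idx in combinations(range(n1 + n2), n1):
        U = sum(ranks[i] for i in idx) - offset
        if abs(U - mu) >= dev_obs - 1e-9:
            count += 1
    return count / total


def mann_whitney_u(x, y, method: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    ``method``: "exact" enumerates the full permutation null (midranks,
    so ties are handled exactly), "normal" uses the tie-corrected normal
    approximation with continuity correction, "auto" picks exact for
    n1 + n2 <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        method = "exact" if x.size + y.size <= 20 else "normal"
    U = _u_statistic(x, y)
    if method == "exact":
        p = _exact_perm_p(x, y, U)
    elif method == "normal":
        _, p = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True)
        p = float(p)
    else:
        raise ValueError("method must be exact, normal or auto")
    return GroupComparison(
        quantity="", U=U, p_value=min(1.0, p),
        median_x=float(np.median(x)), median_y=float(np.median(y)),
        n_x=x.size, n_y=y.size, method=method,
    )


# ---------------------------------------------------------------------------
# kymograph correlation
# ---------------------------------------------------------------------------

def kymograph_correlation(field_a, field_b,
                          restrict_mask: np.ndarray | None = None,
                          min_cells: int = 10) -> CorrelationResult:
    """Pearson r between two kymographs over jointly supported cells.

    ``restrict_mask`` (e.g. a growth-zone mask) further intersects the
    joint support.  Raises if the joint support has fewer than
    ``min_cells`` cells or either field is constant there.
    """
    if not field_a.same_grid(field_b):
        raise ValueError("fields must share grids")
    joint = field_a.mask & field_b.mask
    if restrict_mask is not None:
        joint = joint & restrict_mask
    n = int(joint.sum())
    if n < min_cells:
        raise ValueError(f"joint support has only {n} cells (< {min_cells})")
    a = field_a.values[joint]
    b = field_b.values[joint]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: a field has zero variance")
    r = float(np.corrcoef(a, b)[0, 1])
    return CorrelationResult(r=r, n_cells=n)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

#: Per-plant summary columns compared between treatment groups.
DEFAULT_QUANTITIES = (
    "Tp_regr", "vp_regr", "Tp_curvrate", "vp_curvrate",
    "mean_regr", "mean_regr_pre", "mean_regr_post",
    "mean_curvrate", "mean_curvrate_pre", "mean_curvrate_post",
    "r_coupling",
)


def cohort_compare(per_plant: pd.DataFrame, quantities=None,
                   group_col: str = "group",
                   groups: tuple[str, str] = ("straight", "tilted"),
                   method: str = "auto") -> pd.DataFrame:
    """Straight-vs-tilted Mann-Whitney comparisons of per-plant summaries.

    ``per_plant`` has one row per plant with a ``group`` column and the
    summary quantities (columns missing from the table are skipped).
    Returns a tidy table with one row per quantity: group medians, U, p,
    and sample sizes.  Requires at least 2 plants per group.
    """
    counts = per_plant[group_col].value_counts()
    for g in groups:
        if counts.get(g, 0) < 2:
            raise ValueError(f"need at least 2 plants in group {g!r}")
    quantities = [q for q in (quantities or DEFAULT_QUANTITIES)
                  if q in per_plant.columns]
    rows = []
    for q in quantities:
        gx = per_plant.loc[per_plant[group_col] == groups[0], q].dropna()
        gy = per_plant.loc[per_plant[group_col] == groups[1], q].dropna()
        if len(gx) < 2 or len(gy) < 2:
            continue
        cmp_ = mann_whitney_u(gx.to_numpy(), gy.to_numpy(), method=method)
        rows.append({
            "quantity": q,
            f"median_{groups[0]}": cmp_.median_x,
            f"median_{groups[1]}": cmp_.median_y,
            "U": cmp_.U,
            "p": cmp_.p_value,
            f"n_{groups[0]}": cmp_.n_x,
            f"n_{groups[1]}": cmp_.n_y,
            "method": cmp_.method,
        })
    return pd.DataFrame(rows)
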