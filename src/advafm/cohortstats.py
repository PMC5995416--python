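"""Cohort-level statistics: patient aggregation, two-group tests, binning, FDR.

The analysis contract mirrors a small two-group observational study: all
per-segment / per-image measurements are averaged per patient first, the
low- and high-stiffness groups are compared with nonparametric tests
(Mann-Whitney U with a Hodges-Lehmann location-shift confidence interval,
two-sample Kolmogorov-Smirnov on pooled distributions), clinical covariates
with the classic pooled Student's t, correlations with Spearman's rank
coefficient, and each analysis batch is corrected with the
Benjamini-Hochberg step-up FDR procedure.

The Mann-Whitney test is exact (full null distribution of U by dynamic
programming) for group sizes up to 12 without ties, and uses the
tie-corrected normal approximation otherwise; the Hodges-Lehmann 95% CI is
read off the ordered pairwise differences at the exact (or asymptotic) U
quantiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "BinSpec",
    "DIAMETER_BINS",
    "DPERIOD_BINS",
    "aggregate_per_patient",
    "mann_whitney",
    "ks_two_sample",
    "spearman",
    "students_t",
    "bin_subgroups",
    "bh_adjust",
    "compare_variables",
]

EXACT_MAX_N = 12


@dataclass
class GroupComparison:
    """One two-group test result (statistic, p, optional CI, group summaries)."""

    variable: str
    test: str
    statistic: float
    p_value: float
    p_adjusted: float = math.nan
    ci95: tuple[float, float] | None = None
    n_x: int = 0
    n_y: int = 0
    mean_x: float = math.nan
    sd_x: float = math.nan
    mean_y: float = math.nan
    sd_y: float = math.nan
    degenerate: bool = False


@dataclass
class BinSpec:
    """Subgroup bin edges for a morphometric variable.

    Bins are half-open [lo, hi) except the last, which is closed; values
    outside [first, last] are excluded from percentages but counted.
    """

    variable: str
    edges_nm: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_nm, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing, length >= 2")
        if not self.labels:
            self.labels = tuple(
                f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)
            )
        if len(self.labels) != len(edges) - 1:
            raise ValueError("one label per bin required")


#: Diameter subgroups used in the fibril analysis (nm).
DIAMETER_BINS = BinSpec("diameter", (70.0, 120.0, 150.0, 200.0))
#: D-period subgroups used in the fibril analysis (nm).
DPERIOD_BINS = BinSpec("dperiod", (45.0, 59.0, 70.0, 80.0))


def aggregate_per_patient(
    measurements: pd.DataFrame,
    value_col: str,
    patient_col: str = "patient_id",
    valid_col: str | None = None,
    exclude: Sequence[str] = (),
) -> pd.Series:
    """Unweighted per-patient mean over all of a patient's valid measurements.

    Patients in ``exclude`` (e.g. QC-unusable) are dropped; patients with no
    valid measurements are dropped with a warning.  All measurements pool
    across images: this is the mean over measurements, not a mean of
    image-level means.
    """
    if patient_col not in measurements.columns:
        raise KeyError(f"missing patient key column {patient_col!r}")
    df = measurements
    if exclude:
        df = df[~df[patient_col].isin(set(exclude))]
    if valid_col is not None:
        df = df[df[valid_col].astype(bool)]
    df = df.dropna(subset=[value_col])
    means = df.groupby(patient_col)[value_col].mean()
    empty = set(measurements[patient_col].unique()) - set(means.index) - set(exclude)
    if empty:
        warnings.warn(
            f"patients dropped with zero valid measurements: {sorted(empty)}",
            stacklevel=2,
        )
    return means


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[float, ...]:
    """Null distribution of Mann-Whitney U: count of labelings with each U.

    Recurrence on the largest observation: if it is an x it contributes m to
    U, otherwise nothing -- N(u; n, m) = N(u - m; n-1, m) + N(u; n, m-1).
    """
    if n == 0 or m == 0:
        return (1.0,)
    out = np.zeros(n * m + 1)
    a = _u_counts(n - 1, m)
    out[m : m + len(a)] += a
    b = _u_counts(n, m - 1)
    out[: len(b)] += b
    return tuple(out)


def _exact_u_cdf(n: int, m: int) -> np.ndarray:
    counts = np.asarray(_u_counts(n, m))
    return np.cumsum(counts) / counts.sum()


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    cdf = _exact_u_cdf(n, m)
    u_int = int(round(u))
    lower = cdf[u_int]
    upper = 1.0 - (cdf[u_int - 1] if u_int > 0 else 0.0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (x, y) pairs with x > y, ties counted half."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2.0)


def _hodges_lehmann_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Hodges-Lehmann shift estimate and CI for x - y.

    The estimate is the median of all pairwise differences; the interval is
    the (k, nm+1-k)-th ordered differences with k set by the alpha/2 quantile
    of the null U distribution (exact for small groups, normal otherwise).
    """
    n, m = len(x), len(y)
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    est = float(np.median(diffs))
    nm = n * m
    if n <= EXACT_MAX_N and m <= EXACT_MAX_N:
        cdf = _exact_u_cdf(n, m)
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right"))  # P(U <= k-1) <= a/2
    else:
        z = stats.norm.ppf(alpha / 2.0)
        k = int(math.floor(nm / 2.0 + z * math.sqrt(nm * (n + m + 1) / 12.0)))
    k = max(k, 1)
    return est, (float(diffs[k - 1]), float(diffs[nm - k]))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of x vs y with a Hodges-Lehmann 95% CI.

    Exact null distribution when both groups have at most 12 observations
    and there are no ties across the pooled sample; tie-corrected normal
    approximation (with continuity correction) otherwise.  The CI is on the
    location shift x - y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(u, len(x), len(y))
    else:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    _, ci = _hodges_lehmann_ci(x, y)
    return GroupComparison(
        variable=variable,
        test="mann_whitney",
        statistic=u,
        p_value=p,
        ci95=ci,
        n_x=len(x),
        n_y=len(y),
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)),
    )


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p).

    D is the supremum of the ECDF difference; intended for the pooled
    measurement-level distributions, hence the n >= 8 floor per sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 8 or len(y) < 8:
        raise ValueError("KS test needs at least 8 observations per sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return GroupComparison(
        variable=variable,
        test="ks",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_x=len(x),
        n_y=len(y),
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties).

    The p-value is exact (full permutation null of the rank correlation) for
    n <= 8 without ties, where the usual t-approximation is visibly off;
    larger or tied samples use the t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must be paired")
    if len(x) < 5:
        raise ValueError("Spearman correlation needs at least 5 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    rho, p = stats.spearmanr(x, y)
    n = len(x)
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 8 and no_ties:
        # exact two-sided p over all n! rank pairings via sum of squared
        # rank differences: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2_obs = float(np.sum((rx - ry) ** 2))
        base = np.arange(1, n + 1, dtype=float)
        d2_null = np.array(
            [np.sum((base - np.asarray(perm)) ** 2) for perm in permutations(base)]
        )
        denom = n * (n * n - 1) / 6.0
        rho_null = 1.0 - d2_null / denom
        rho_obs = 1.0 - d2_obs / denom
        p = float(np.mean(np.abs(rho_null) >= abs(rho_obs) - 1e-12))
    return float(rho), float(p)


def students_t(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Classic two-sided pooled-variance Student's t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    var_x, var_y = x.var(ddof=1), y.var(ddof=1)
    degenerate = False
    if var_x == 0 and var_y == 0:
        degenerate = True
        if x.mean() == y.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf if x.mean() > y.mean() else -math.inf, 0.0
    else:
        res = stats.ttest_ind(x, y, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        variable=variable,
        test="t",
        statistic=t_stat,
        p_value=p,
        n_x=len(x),
        n_y=len(y),
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)),
        degenerate=degenerate,
    )


def bin_subgroups(
    values_nm: Sequence[float], spec: BinSpec
) -> tuple[pd.DataFrame, int]:
    """Assign measurements to subgroup bins and summarize each bin.

    Returns a per-bin table (label, n, percentage over in-range values,
    mean, sd) and the count of out-of-range values.  Bins are half-open
    [lo, hi) except the last, which includes its upper edge.
    """
    values = np.asarray(values_nm, dtype=float)
    edges = np.asarray(spec.edges_nm)
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2  # closed last bin
    in_range = (idx >= 0) & (idx <= len(edges) - 2)
    n_excluded = int(np.count_nonzero(~in_range))
    n_in = int(np.count_nonzero(in_range))
    rows = []
    for b, label in enumerate(spec.labels):
        sel = values[in_range & (idx == b)]
        rows.append(
            {
                "bin": label,
                "n": int(sel.size),
                "percentage": 100.0 * sel.size / n_in if n_in else math.nan,
                "mean": float(sel.mean()) if sel.size else math.nan,
                "sd": float(sel.std(ddof=1)) if sel.size > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows), n_excluded


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_variables(
    patients: pd.DataFrame,
    variables: Sequence[str],
    test: str = "mann_whitney",
    group_col: str = "group",
    low: str = "low",
    high: str = "high",
) -> pd.DataFrame:
    """Run one two-group test per variable and BH-adjust within the batch.

    Each test compares low vs high group values of a patient-level variable;
    the returned table mirrors the study's summary-table layout (group n /
    mean / SD, statistic, 95% CI where available, raw and adjusted p).
    """
    test_funcs = {"mann_whitney": mann_whitney, "t": students_t, "ks": ks_two_sample}
    if test not in test_funcs:
        raise ValueError(f"unknown test {test!r}")
    results: list[GroupComparison] = []
    for var in variables:
        x = patients.loc[patients[group_col] == low, var].dropna().to_numpy()
        y = patients.loc[patients[group_col] == high, var].dropna().to_numpy()
        results.append(test_funcs[test](x, y, variable=var))
    adjusted = bh_adjust([r.p_value for r in results])
    rows = []
    for r, adj in zip(results, adjusted):
        r.p_adjusted = float(adj)
        rows.append(
            {
                "variable": r.variable,
                "test": r.test,
                "n_low": r.n_x,
                "mean_low": r.mean_x,
                "sd_low": r.sd_x,
                "n_high": r.n_y,
                "mean_high": r.mean_y,
                "sd_high": r.sd_y,
                "statistic": r.statistic,
                "ci95_low": r.ci95[0] if r.ci95 else math.nan,
                "ci95_high": r.ci95[1] if r.ci95 else math.nan,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
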