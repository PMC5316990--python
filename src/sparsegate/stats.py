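"""Statistical battery for group comparisons of imaging and patch data.

Covers the study's decision pipeline: Kolmogorov-Smirnov normality
screening, Brown-Forsythe variance testing with a log(value+1) transform
for heteroscedastic percentages, Kruskal-Wallis with Dunn's post hoc for
non-normal data, one-way ANOVA with Dunnett's or Tukey's post hoc
otherwise, Welch t-tests, Fisher's exact test for contingency tables,
two-sample KS for distribution comparisons, and ROUT robust outlier
elimination at a configurable false-discovery rate.

Standard tests delegate to scipy; the Dunn post hoc, the ROUT procedure and
the auto_compare driver are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsParams",
    "TestResult",
    "log1p_transform",
    "log1p_inverse",
    "ks_normality",
    "brown_forsythe",
    "kruskal_wallis",
    "dunn_posthoc",
    "one_way_anova",
    "fisher_exact",
    "rout_outliers",
    "ks_two_sample",
    "auto_compare_groups",
]


@dataclass(frozen=True)
class StatsParams:
    """alpha: significance level; rout_q: ROUT FDR; transform: none|log1p;
    posthoc: dunn|dunnett|tukey (dunnett compares each group to the first)."""

    alpha: float = 0.05
    rout_q: float = 0.01
    transform: str = "none"
    posthoc: str = "dunnett"  # dunnett | tukey | none

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.rout_q < 1:
            raise ValueError("alpha and rout_q must lie in (0,1)")


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    posthoc: dict[tuple[int, int], float] | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p must lie in [0,1]")


def log1p_transform(values: Sequence[float]) -> np.ndarray:
    """Elementwise ln(value + 1); used to equalize variance of percentages."""
    vals = np.asarray(values, dtype=float)
    if np.any(vals < -1):
        raise ValueError("log1p_transform requires values > -1")
    return np.log1p(vals)


def log1p_inverse(values: Sequence[float]) -> np.ndarray:
    return np.expm1(np.asarray(values, dtype=float))


def ks_normality(values: Sequence[float]) -> TestResult:
    """One-sample KS against a normal with the sample's mean and SD."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 5:
        raise ValueError("need at least 5 values")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    res = sps.kstest(vals, "norm", args=(vals.mean(), sd))
    return TestResult(float(res.statistic), float(res.pvalue), method="ks-normality")


def brown_forsythe(groups: Sequence[Sequence[float]]) -> TestResult:
    """Brown-Forsythe test of equal variances: ANOVA on |x − group median|."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need ≥ 2 groups with ≥ 2 values each")
    if all(len(np.unique(np.abs(g - np.median(g)))) == 1 for g in arrays):
        return TestResult(0.0, 1.0, method="brown-forsythe")
    stat, p = sps.levene(*arrays, center="median")
    k, n = len(arrays), sum(map(len, arrays))
    return TestResult(float(stat), float(p), df=(k - 1, n - k), method="brown-forsythe")


def kruskal_wallis(
    groups: Sequence[Sequence[float]], posthoc: bool = True, adjust: str = "bonferroni"
) -> TestResult:
    """Kruskal-Wallis H (tie-corrected, chi-square p) with Dunn's post hoc."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, df=len(arrays) - 1, method="kruskal-wallis")
    stat, p = sps.kruskal(*arrays)
    ph = dunn_posthoc(arrays, adjust=adjust) if posthoc else None
    return TestResult(float(stat), float(p), df=len(arrays) - 1,
                      posthoc=ph, method="kruskal-wallis")


def dunn_posthoc(
    groups: Sequence[Sequence[float]], adjust: str = "bonferroni"
) -> dict[tuple[int, int], float]:
    """Dunn's rank-mean z comparisons for all group pairs.

    z_ij = |R̄_i − R̄_j| / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    correction T = Σ(t³−t) / (12(N−1)).  Two-sided normal p-values with a
    Bonferroni family adjustment by default ("none" disables it).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start: start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    m = len(arrays) * (len(arrays) - 1) // 2
    out: dict[tuple[int, int], float] = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(z)
            if adjust == "bonferroni":
                p = min(1.0, p * m)
            out[(i, j)] = float(p)
    return out


def one_way_anova(
    groups: Sequence[Sequence[float]],
    posthoc: str = "dunnett",
    control_index: int = 0,
) -> TestResult:
    """One-way ANOVA with Dunnett's many-to-one or Tukey's all-pairs post hoc.

    Dunnett compares every group against ``groups[control_index]``; its
    adjusted p-values integrate the multivariate-t null distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need ≥ 2 groups with ≥ 2 values each")
    if all(g.std(ddof=1) == 0 for g in arrays):
        raise ValueError("zero within-group variance everywhere")
    stat, p = sps.f_oneway(*arrays)
    k, n = len(arrays), sum(map(len, arrays))
    ph: dict[tuple[int, int], float] | None = None
    if posthoc == "dunnett" and len(arrays) > 1:
        treatments = [g for i, g in enumerate(arrays) if i != control_index]
        idx = [i for i in range(len(arrays)) if i != control_index]
        res = sps.dunnett(*treatments, control=arrays[control_index],
                          random_state=np.random.default_rng(0))
        ph = {(control_index, i): float(pv) for i, pv in zip(idx, res.pvalue)}
    elif posthoc == "tukey":
        res = sps.tukey_hsd(*arrays)
        ph = {(i, j): float(res.pvalue[i, j])
              for i in range(k) for j in range(i + 1, k)}
    return TestResult(float(stat), float(p), df=(k - 1, n - k),
                      posthoc=ph, method="one-way-anova")


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 table.

    Sum of hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one (the usual
    (1 + 1e-7) tie slack).  Empty margins give p = 1.
    """
    tbl = np.asarray(table, dtype=np.int64)
    if tbl.shape != (2, 2) or np.any(tbl < 0):
        raise ValueError("table must be 2×2 with non-negative integer counts")
    if np.any(tbl.sum(axis=0) == 0) or np.any(tbl.sum(axis=1) == 0):
        return 1.0
    n = int(tbl.sum())
    r1 = int(tbl[0].sum())
    c1 = int(tbl[:, 0].sum())
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(tbl[0, 0])
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(1.0, p)


def rout_outliers(
    values: Sequence[float], q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """ROUT outlier elimination for a single-group (constant-fit) sample.

    Residuals from the median are scaled by the robust standard deviation
    of the residuals (68.27th percentile of |residual|, with an n/(n−1)
    small-sample correction).  Residual t-tail probabilities are compared,
    largest residuals first, against a Benjamini-Hochberg-style boundary at
    false-discovery rate ``q``; the maximal extreme prefix passing the
    boundary is flagged.  Returns (kept values, outlier flags).
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    flags = np.zeros(n, dtype=bool)
    if not 0 < q < 1:
        raise ValueError("q must lie in (0,1)")
    if n < 5:
        warnings.warn("fewer than 5 values; no outlier removal", stacklevel=2)
        return vals, flags
    resid = np.abs(vals - np.median(vals))
    rsdr = float(np.percentile(resid, 68.27)) * n / (n - 1)
    if rsdr == 0:
        return vals, flags
    tvals = resid / rsdr
    pvals = 2.0 * sps.t.sf(tvals, df=n - 1)
    order = np.argsort(-resid, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= q * rank / n:
            k_max = rank
    flags[order[:k_max]] = True
    return vals[~flags], flags


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided two-sample KS: D = max ECDF gap, asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), method="ks-2samp")


def auto_compare_groups(
    groups: Sequence[Sequence[float]], params: StatsParams | None = None
) -> TestResult:
    """Decision pipeline for multi-group comparison.

    KS-screen each group for normality; any departure routes the comparison
    to Kruskal-Wallis with Dunn's post hoc.  Otherwise a Brown-Forsythe test
    checks variance homogeneity; inequality triggers a log(value+1)
    transform before the one-way ANOVA with the configured post hoc.
    """
    params = params or StatsParams()
    arrays = [np.asarray(g, dtype=float) for g in groups]
    normal = True
    for g in arrays:
        try:
            if ks_normality(g).p < params.alpha:
                normal = False
                break
        except ValueError:
            normal = False
            break
    if not normal:
        return kruskal_wallis(arrays, posthoc=params.posthoc != "none")
    bf = brown_forsythe(arrays)
    nonnegative = all(g.min() >= 0 for g in arrays)
    if nonnegative and (bf.p < params.alpha or params.transform == "log1p"):
        arrays = [log1p_transform(g) for g in arrays]
    return one_way_anova(arrays, posthoc=params.posthoc)
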