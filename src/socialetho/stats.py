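"""Nonparametric statistical toolkit with fully pinned conventions.

The tests mirror common practice in behavioral work implemented on top of R's
``stats`` ecosystem:

* Mann-Whitney U for two-sample comparisons; "paired Mann-Whitney" and the
  one-sample comparison to a null median are the Wilcoxon signed-rank test
  (the established behavior of the paired option in ``wilcox.test``), with
  zero differences dropped;
* two-sample Kolmogorov-Smirnov for distribution/time-course comparisons;
* Kruskal-Wallis omnibus with post-hoc Dunn's tests (tie-corrected z), BH
  adjustment across all pairs and a compact letter display;
* exact binomial tests for one-sample frequencies (two-sided by the
  sum-of-smaller-probabilities rule) and Fisher's exact test for two-sample
  frequency comparisons (a two-proportion z-test is offered as an
  alternative mode);
* BH (Benjamini-Hochberg) step-up adjustment;
* Cohen's d with a normal-approximation 95% CI;
* Tukey fences (Q3 + 1.5*IQR / Q1 - 1.5*IQR, quartiles by linear
  interpolation) for outlier *flagging only* — flagged values are retained in
  every quantification;
* least-squares linear fits with Pearson's r and its t-distribution p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from string import ascii_lowercase

import numpy as np
import networkx as nx
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .core import ValidationError

__all__ = [
    "StatsParams",
    "TestResult",
    "mann_whitney",
    "ks_two_sample",
    "kruskal_dunn",
    "assign_letters",
    "binomial_tests",
    "bh_adjust",
    "cohens_d",
    "tukey_outliers",
    "pearson_linfit",
]


@dataclass(frozen=True)
class StatsParams:
    """alpha: significance level; tukey_k: fence multiplier; exact_max_n:
    combined sample size at or below which rank tests use exact enumeration
    (ties force the approximation); mt_method: multiple-testing method."""

    alpha: float = 0.05
    tukey_k: float = 1.5
    exact_max_n: int = 12
    mt_method: str = "fdr_bh"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.tukey_k <= 0:
            raise ValidationError("tukey_k must be positive")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    paired: bool = False
    adjusted_p: float | None = None
    effect_size: float | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValidationError("p-value outside [0, 1]")


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    x,
    y=None,
    null_median: float = 0.0,
    paired: bool = False,
    alternative: str = "two-sided",
    params: StatsParams | None = None,
) -> TestResult:
    """Rank test for two samples or one sample against a null median.

    Unpaired two-sample -> Mann-Whitney U. Paired two-sample and one-sample
    (``y=None``, differences ``x - null_median``) -> Wilcoxon signed-rank,
    with zero differences dropped. Exact p by enumeration when the combined
    sample size is <= ``params.exact_max_n`` and there are no ties (no zero
    differences for the signed-rank case); otherwise the normal approximation
    with tie and continuity corrections.
    """
    params = params or StatsParams()
    x = np.asarray(x, dtype=float)
    if y is not None and not paired:
        y = np.asarray(y, dtype=float)
        if len(x) < 1 or len(y) < 1:
            raise ValidationError("each sample needs n >= 1")
        exact = (len(x) + len(y)) <= params.exact_max_n and not _has_ties(x, y)
        res = sps.mannwhitneyu(
            x, y, alternative=alternative,
            method="exact" if exact else "asymptotic",
        )
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            method="Mann-Whitney U (%s)" % ("exact" if exact else "normal approx."),
            n=(len(x), len(y)),
            paired=False,
        )
    # paired / one-sample -> signed rank on differences
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValidationError("paired test requires equal lengths")
        d = x - y
    else:
        d = x - null_median
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return TestResult(
            statistic=0.0, p_value=1.0,
            method="Wilcoxon signed-rank (degenerate: all differences zero)",
            n=(len(d),), paired=y is not None, degenerate=True,
        )
    exact = len(nonzero) <= params.exact_max_n and not _has_ties(np.abs(nonzero))
    res = sps.wilcoxon(
        nonzero, alternative=alternative,
        method="exact" if exact else "approx",
        correction=not exact,
        zero_method="wilcox",
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="Wilcoxon signed-rank (%s)" % ("exact" if exact else "normal approx."),
        n=(len(d),),
        paired=y is not None,
        extra={"n_nonzero": len(nonzero)},
    )


def ks_two_sample(x, y, alternative: str = "two-sided") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup \\|ECDF_x - ECDF_y\\|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("each sample needs n >= 1")
    res = sps.ks_2samp(x, y, alternative=alternative, method="auto")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="two-sample Kolmogorov-Smirnov",
        n=(len(x), len(y)),
    )


def _dunn_z(ranks_mean, n, N, tie_term, i, j):
    se = np.sqrt(
        (N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)))
        * (1.0 / n[i] + 1.0 / n[j])
    )
    return (ranks_mean[i] - ranks_mean[j]) / se


def kruskal_dunn(
    groups: list, params: StatsParams | None = None
) -> tuple[TestResult, list[dict], list[str]]:
    """Kruskal-Wallis omnibus plus post-hoc Dunn's tests with BH and letters.

    Dunn's z for groups i, j uses the mean pooled ranks and the tie-corrected
    standard error sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)] with
    T = sum(t^3 - t) over tie groups; two-sided p from the normal, BH-adjusted
    across all k(k-1)/2 pairs. Letters come from :func:`assign_letters` on the
    adjusted significance matrix: groups that share no letter differ
    significantly.
    """
    params = params or StatsParams()
    k = len(groups)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in groups):
        raise ValidationError("each group needs n >= 1")
    omni = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    n = [len(g) for g in groups]
    starts = np.cumsum([0] + n)
    rmean = [ranks[starts[i]:starts[i + 1]].mean() for i in range(k)]
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts))
    pairwise = []
    for i, j in combinations(range(k), 2):
        z = _dunn_z(rmean, n, N, tie_term, i, j)
        p = 2 * sps.norm.sf(abs(z))
        pairwise.append({"i": i, "j": j, "z": float(z), "p": float(p)})
    adj = bh_adjust([d["p"] for d in pairwise]) if pairwise else []
    for d, a in zip(pairwise, adj):
        d["p_adj"] = float(a)
    sig = np.zeros((k, k), dtype=bool)
    for d in pairwise:
        s = d["p_adj"] < params.alpha
        sig[d["i"], d["j"]] = sig[d["j"], d["i"]] = s
    letters = assign_letters(sig)
    omnibus = TestResult(
        statistic=float(omni.statistic),
        p_value=float(omni.pvalue),
        method="Kruskal-Wallis",
        n=tuple(n),
    )
    return omnibus, pairwise, letters


def assign_letters(sig_matrix: np.ndarray) -> list[str]:
    """Compact letter display from a k x k boolean significance matrix.

    Groups not significantly different share at least one letter; groups
    significantly different share none. Letters correspond to an irredundant
    cover of the non-significance graph by maximal cliques (insert-and-absorb)
    and are named a, b, c, ... in order of the first group using each.
    Deterministic.
    """
    sig = np.asarray(sig_matrix, dtype=bool)
    if sig.ndim != 2 or sig.shape[0] != sig.shape[1]:
        raise ValidationError("significance matrix must be square")
    if not np.array_equal(sig, sig.T):
        raise ValidationError("significance matrix must be symmetric")
    if sig.diagonal().any():
        raise ValidationError("diagonal must be False (a group differs from itself?)")
    k = sig.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i, j in combinations(range(k), 2):
        if not sig[i, j]:
            g.add_edge(i, j)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort()
    # absorb: drop any clique whose vertices and non-sig pairs are covered by the rest
    def covered(drop: int) -> bool:
        rest = [c for idx, c in enumerate(cliques) if idx != drop]
        verts = set().union(*rest) if rest else set()
        if set(cliques[drop]) - verts:
            return False
        need = set(combinations(cliques[drop], 2))
        have = {p for c in rest for p in combinations(c, 2)}
        return need <= have

    idx = 0
    while idx < len(cliques):
        if len(cliques) > 1 and covered(idx):
            cliques.pop(idx)
        else:
            idx += 1
    cliques.sort(key=lambda c: c[0])
    letters = [""] * k
    for letter, clique in zip(ascii_lowercase, cliques):
        for v in clique:
            letters[v] += letter
    return letters


def binomial_tests(
    k: int,
    n: int,
    p0: float | None = None,
    k2: int | None = None,
    n2: int | None = None,
    alternative: str = "two-sided",
    mode: str = "fisher",
) -> TestResult:
    """Frequency tests for binary outcomes.

    One-sample (``p0`` given): exact binomial test, two-sided p by summing
    all outcome probabilities <= P(observed). Two-sample (``k2, n2`` given):
    Fisher's exact test on the 2x2 table by default, or a two-proportion
    z-test with ``mode="ztest"``.
    """
    if not (0 <= k <= n and n >= 1):
        raise ValidationError("invalid counts")
    if p0 is not None:
        res = sps.binomtest(k, n, p0, alternative=alternative)
        return TestResult(
            statistic=float(k), p_value=float(res.pvalue),
            method="exact binomial", n=(n,),
        )
    if k2 is None or n2 is None:
        raise ValidationError("need either p0 or (k2, n2)")
    if not (0 <= k2 <= n2 and n2 >= 1):
        raise ValidationError("invalid counts")
    if mode == "fisher":
        table = [[k, n - k], [k2, n2 - k2]]
        stat, p = sps.fisher_exact(table, alternative=alternative)
        return TestResult(
            statistic=float(stat), p_value=float(p),
            method="Fisher exact (two-sample frequency)", n=(n, n2),
        )
    if mode == "ztest":
        stat, p = proportions_ztest(
            [k, k2], [n, n2],
            alternative={"two-sided": "two-sided", "less": "smaller",
                         "greater": "larger"}[alternative],
        )
        return TestResult(
            statistic=float(stat), p_value=float(p),
            method="two-proportion z", n=(n, n2),
        )
    raise ValidationError(f"unknown mode {mode!r}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def cohens_d(x, y, alpha: float = 0.05) -> TestResult:
    """Cohen's d with pooled standard deviation and a normal-approximation CI.

    d = (mean_x - mean_y) / s_pooled, s_pooled^2 = [(n1-1)s1^2 + (n2-1)s2^2]
    / (n1+n2-2); the CI uses se = sqrt[(n1+n2)/(n1 n2) + d^2/(2(n1+n2-2))].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return TestResult(
            statistic=np.nan, p_value=np.nan, method="Cohen's d",
            n=(n1, n2), degenerate=True,
        )
    d = (x.mean() - y.mean()) / np.sqrt(s2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    z = sps.norm.ppf(1 - alpha / 2)
    return TestResult(
        statistic=float(d), p_value=np.nan, method="Cohen's d", n=(n1, n2),
        effect_size=float(d),
        extra={"ci_low": float(d - z * se), "ci_high": float(d + z * se)},
    )


def tukey_outliers(x, params: StatsParams | None = None) -> np.ndarray:
    """Flag values beyond the Tukey fences; never removes anything.

    Fences are Q1 - k*IQR and Q3 + k*IQR (strict >/<) with quartiles by
    linear interpolation between order statistics. With n < 4 no flags are
    raised (quartiles are not meaningful).
    """
    params = params or StatsParams()
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        return np.zeros(len(x), dtype=bool)
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation (default)
    iqr = q3 - q1
    return (x > q3 + params.tukey_k * iqr) | (x < q1 - params.tukey_k * iqr)


def pearson_linfit(x, y) -> dict:
    """Least-squares line plus Pearson correlation.

    Returns slope, intercept, r and the two-sided p for r from the
    t-distribution with n - 2 df. Zero variance in x is an error; constant y
    is returned with r = 0 and flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("need n >= 3 equal-length vectors")
    if np.var(x) == 0:
        raise ValidationError("zero variance in x")
    if np.var(y) == 0:
        return {
            "slope": 0.0, "intercept": float(y.mean()), "r": 0.0,
            "p": np.nan, "degenerate": True,
        }
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "degenerate": False,
    }
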