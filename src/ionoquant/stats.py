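"""Adaptive group-comparison scheme over count data.

The comparison scheme mirrors common practice in zebrafish quantification
studies: normality of each group is assessed with a Kolmogorov–Smirnov
test; two groups are then compared by an unpaired two-tailed t-test when
both pass, and by a two-tailed Mann–Whitney U-test otherwise; paired
designs use the Wilcoxon matched-pairs signed-rank test.  More than two
groups are compared with one-way ANOVA or Kruskal–Wallis as omnibus,
followed by Dunnett's test versus a control or Dunn's all-pairs test.
P-values below 0.05 are considered significant.

Caveat: a KS test with mean and s.d. estimated from the sample is
anticonservative (the Lilliefors situation); the plain KS gate is the
default for fidelity to that practice, with ``method="lilliefors"``
available for the corrected version.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["StatResult", "ks_normality", "mann_whitney",
           "compare_two_groups", "compare_multi_groups", "dunn_posthoc"]

ALPHA = 0.05


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    sem: float  # sd / sqrt(n)
    normality_p: Optional[float] = None


@dataclass
class StatResult:
    comparison: str
    test: str
    statistic: float
    p: float
    groups: list[GroupSummary] = field(default_factory=list)
    alpha: float = ALPHA
    posthoc: Optional[dict[str, float]] = None  # comparison label -> adjusted p
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "alpha": self.alpha,
            "significant": self.significant,
            "groups": [{"name": g.name, "n": g.n, "mean": g.mean,
                        "sem": g.sem, "normality_p": g.normality_p}
                       for g in self.groups],
            "posthoc": self.posthoc,
        }


def _summary(name: str, x: np.ndarray, norm_p: Optional[float]) -> GroupSummary:
    return GroupSummary(name=name, n=len(x), mean=float(np.mean(x)),
                        sem=float(np.std(x, ddof=1) / np.sqrt(len(x)))
                        if len(x) > 1 else float("nan"),
                        normality_p=norm_p)


def ks_normality(sample: Sequence[float],
                 method: Literal["ks", "lilliefors"] = "ks") -> float:
    """Normality p-value for one sample.

    ``"ks"`` runs a Kolmogorov–Smirnov test against a normal distribution
    with the sample's own mean and s.d. (anticonservative, see module
    docstring); ``"lilliefors"`` applies the correction for estimated
    parameters.  Samples of fewer than 5 values trigger a warning — the
    test has essentially no power there.  A zero-variance sample is an
    error.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined (sd = 0)")
    if len(x) < 5:
        warnings.warn("normality test on n < 5 is unreliable", stacklevel=2)
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors
        _, p = lilliefors(x, dist="norm")
        return float(p)
    _, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U: exact for n<=8 without ties, else normal
    approximation with tie correction."""
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= 8 and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        label = "MannWhitney(exact)"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        label = "MannWhitney(asymptotic)"
    return float(res.statistic), float(res.pvalue), label


def compare_two_groups(a: Sequence[float], b: Sequence[float],
                       paired: bool = False, alpha: float = ALPHA,
                       names: tuple[str, str] = ("A", "B"),
                       normality_method: Literal["ks", "lilliefors"] = "ks",
                       normality_alpha: float = 0.05) -> StatResult:
    """Compare two groups with the adaptive test-selection rule.

    Unpaired: t-test if both groups pass the normality gate, otherwise
    Mann–Whitney U.  Paired: Wilcoxon matched-pairs signed-rank (no gate;
    the paired comparisons here are ratio-like and not assumed normal).
    All tests are two-sided.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need n >= 3 per group")
    comparison = f"{names[0]} vs {names[1]}"

    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            return StatResult(comparison=comparison, test="Wilcoxon_paired",
                              statistic=float("nan"), p=1.0, alpha=alpha,
                              degenerate=True,
                              groups=[_summary(names[0], a, None),
                                      _summary(names[1], b, None)])
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return StatResult(comparison=comparison, test="Wilcoxon_paired",
                          statistic=float(res.statistic), p=float(res.pvalue),
                          alpha=alpha,
                          groups=[_summary(names[0], a, None),
                                  _summary(names[1], b, None)])

    try:
        pa = ks_normality(a, method=normality_method)
        pb = ks_normality(b, method=normality_method)
    except ValueError:  # constant group: clearly not treatable as normal
        pa = pb = 0.0
    if pa > normality_alpha and pb > normality_alpha:
        res = stats.ttest_ind(a, b)
        test, statistic, p = "t", float(res.statistic), float(res.pvalue)
    else:
        statistic, p, test = mann_whitney(a, b)
    return StatResult(comparison=comparison, test=test, statistic=statistic,
                      p=p, alpha=alpha,
                      groups=[_summary(names[0], a, pa),
                              _summary(names[1], b, pb)])


def _dunn_z(groups: list[np.ndarray], i: int, j: int,
            ranksums: list[float], tie_term: float, n_total: int) -> float:
    ni, nj = len(groups[i]), len(groups[j])
    mean_i = ranksums[i] / ni
    mean_j = ranksums[j] / nj
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj)
    return (mean_i - mean_j) / np.sqrt(var)


def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjust: Literal["holm", "bonferroni", "none"] = "holm"
                 ) -> dict[str, float]:
    """Dunn's all-pairs rank-based post hoc with tie correction.

    Pools all observations, ranks them once, and compares mean ranks with
    a z statistic; adjusted p-values by Holm (default) or Bonferroni.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term: sum(t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    ranksums, start = [], 0
    for arr in arrays:
        ranksums.append(float(ranks[start:start + len(arr)].sum()))
        start += len(arr)

    raw = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        z = _dunn_z(arrays, i, j, ranksums, tie_term, n_total)
        raw[f"{names[i]} vs {names[j]}"] = 2 * stats.norm.sf(abs(z))
    if adjust == "none":
        return raw
    labels = list(raw)
    pvals = np.array([raw[k] for k in labels])
    if adjust == "bonferroni":
        adj = np.minimum(pvals * len(pvals), 1.0)
    else:  # holm step-down
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, pvals[idx] * (len(pvals) - rank))
            adj[idx] = min(running, 1.0)
    return dict(zip(labels, adj))


def compare_multi_groups(groups: dict[str, Sequence[float]],
                         method: Literal["anova_dunnett", "anova_dunn",
                                         "kw_dunn"] = "anova_dunnett",
                         control: Optional[str] = None,
                         alpha: float = ALPHA) -> StatResult:
    """Omnibus comparison of three or more groups plus a post hoc.

    ``anova_dunnett`` — one-way ANOVA, then Dunnett's many-to-one test
    against ``control`` (required); ``anova_dunn`` — ANOVA omnibus with
    Dunn's all-pairs post hoc; ``kw_dunn`` — Kruskal–Wallis omnibus with
    Dunn's all-pairs post hoc.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    names = list(groups)
    arrays = {n: np.asarray(groups[n], dtype=float) for n in names}
    values = list(arrays.values())

    if method in ("anova_dunnett", "anova_dunn"):
        res = stats.f_oneway(*values)
        omnibus = "ANOVA"
    elif method == "kw_dunn":
        res = stats.kruskal(*values)
        omnibus = "KruskalWallis"
    else:
        raise ValueError(f"unknown method {method!r}")

    if method == "anova_dunnett":
        if control is None:
            raise ValueError("Dunnett's test requires a control group name")
        if control not in arrays:
            raise ValueError(f"control group {control!r} not among groups")
        others = [n for n in names if n != control]
        dres = stats.dunnett(*[arrays[n] for n in others],
                             control=arrays[control])
        posthoc = {f"{n} vs {control}": float(p)
                   for n, p in zip(others, dres.pvalue)}
        test = "ANOVA+Dunnett"
    else:
        posthoc = dunn_posthoc(arrays)
        test = f"{omnibus}+Dunn"

    return StatResult(
        comparison=" vs ".join(names), test=test,
        statistic=float(res.statistic), p=float(res.pvalue), alpha=alpha,
        posthoc=posthoc,
        groups=[_summary(n, arrays[n], None) for n in names])
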