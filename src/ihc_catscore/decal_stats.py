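"""Group-comparison statistics for the decalcification time course.

Staining measurements at decalcification times 0/1/6/24 h are compared as
independent groups.  For approximately normal markers: one-way ANOVA,
confirmed by Welch's heteroscedastic ANOVA on the rank-transformed data,
followed by Tukey studentized-range pairwise comparisons.  For non-normal
markers (p53 in the original study design): Kruskal-Wallis, followed by
pairwise Wilcoxon rank-sum tests at a Bonferroni-adjusted level
(0.05 / C(k,2); 0.05/6 ≈ 0.0083 for four time points).

Textbook procedures delegate to scipy.stats; Welch's ANOVA, which scipy does
not provide for k groups, is implemented from the standard formula.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupComparisonResult",
    "PairResult",
    "anova_oneway",
    "welch_anova",
    "welch_anova_on_ranks",
    "tukey_hsd",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
    "decal_battery",
]


@dataclass(frozen=True)
class PairResult:
    pair: tuple[int, int]
    pvalue: float
    significant: bool


@dataclass(frozen=True)
class GroupComparisonResult:
    test: str
    statistic: float
    pvalue: float
    pairwise: tuple[PairResult, ...] = ()
    adjustment: str | None = None
    alpha: float | None = None
    #: per-comparison significance level after adjustment (Bonferroni)
    per_pair_alpha: float | None = None
    n_comparisons: int | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "degenerate": self.degenerate,
        }
        if self.adjustment:
            d["adjustment"] = self.adjustment
            d["alpha"] = self.alpha
        if self.per_pair_alpha is not None:
            d["per_pair_alpha"] = self.per_pair_alpha
            d["n_comparisons"] = self.n_comparisons
        if self.pairwise:
            d["pairwise"] = [
                {"pair": list(p.pair), "pvalue": p.pvalue, "significant": p.significant}
                for p in self.pairwise
            ]
        return d


def _as_groups(groups, min_size=1, min_groups=2):
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < min_groups:
        raise ValidationError(f"need at least {min_groups} groups, got {len(gs)}")
    for i, g in enumerate(gs):
        if g.size < min_size:
            raise ValidationError(f"group {i} has {g.size} < {min_size} observations")
        if not np.all(np.isfinite(g)):
            raise ValidationError(f"group {i} contains non-finite values")
    return gs


def _all_tied(gs) -> bool:
    pooled = np.concatenate(gs)
    return np.unique(pooled).size == 1


def anova_oneway(groups) -> GroupComparisonResult:
    """Classical one-way ANOVA (F statistic, p from the F distribution)."""
    gs = _as_groups(groups, min_size=2)
    if _all_tied(gs):
        return GroupComparisonResult("anova", float("nan"), float("nan"), degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*gs)
    degenerate = not (np.isfinite(f) and np.isfinite(p))
    return GroupComparisonResult("anova", float(f), float(p), degenerate=degenerate)


def welch_anova(groups) -> GroupComparisonResult:
    """Welch's heteroscedastic one-way ANOVA (unequal variances allowed)."""
    gs = _as_groups(groups, min_size=2)
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    if np.any(v == 0):
        return GroupComparisonResult("welch_anova", float("nan"), float("nan"), degenerate=True)
    w = n / v
    sw = w.sum()
    grand = (w * m).sum() / sw
    a = ((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = (((1 - w / sw) ** 2) / (n - 1)).sum()
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return GroupComparisonResult("welch_anova", float(f), p)


def welch_anova_on_ranks(groups) -> GroupComparisonResult:
    """Welch's ANOVA applied to mid-ranks of the pooled sample.

    Rank transformation makes the test invariant to strictly monotone
    transformations of the data; Welch's correction guards against unequal
    group variances of the ranks.  Degenerate (all observations tied, or a
    group with constant ranks) inputs are flagged rather than tested.
    """
    gs = _as_groups(groups, min_size=2)
    if _all_tied(gs):
        return GroupComparisonResult(
            "welch_anova_on_ranks", float("nan"), float("nan"), degenerate=True
        )
    pooled = np.concatenate(gs)
    ranks = stats.rankdata(pooled)
    sizes = np.cumsum([g.size for g in gs])[:-1]
    rank_groups = np.split(ranks, sizes)
    res = welch_anova(rank_groups)
    return GroupComparisonResult(
        "welch_anova_on_ranks", res.statistic, res.pvalue, degenerate=res.degenerate
    )


def tukey_hsd(groups, alpha: float = 0.05) -> GroupComparisonResult:
    """Tukey studentized-range pairwise comparisons following ANOVA."""
    gs = _as_groups(groups, min_size=2)
    if _all_tied(gs):
        return GroupComparisonResult("tukey_hsd", float("nan"), float("nan"), degenerate=True)
    res = stats.tukey_hsd(*gs)
    pairs = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        p = float(res.pvalue[i, j])
        pairs.append(PairResult((i, j), p, p < alpha))
    anova = anova_oneway(gs)
    return GroupComparisonResult(
        "tukey_hsd",
        anova.statistic,
        anova.pvalue,
        pairwise=tuple(pairs),
        adjustment="tukey",
        alpha=alpha,
    )


def _kruskal_h(gs) -> float:
    """Tie-corrected Kruskal-Wallis H for a list of groups."""
    pooled = np.concatenate(gs)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = np.cumsum([g.size for g in gs])[:-1]
    rgs = np.split(ranks, sizes)
    h = 12.0 / (n * (n + 1)) * sum(rg.sum() ** 2 / rg.size for rg in rgs) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else float("nan")


def kruskal_wallis(groups, method: str = "chi2") -> GroupComparisonResult:
    """Kruskal-Wallis H test.

    ``method="chi2"`` (default) takes p from the chi-square approximation
    with k-1 degrees of freedom (tie-corrected H, via scipy).
    ``method="exact"`` enumerates every permutation of the pooled sample into
    the observed group sizes — exact, but only feasible for tiny samples
    (total n <= 10).
    """
    gs = _as_groups(groups, min_size=1)
    if sum(g.size for g in gs) < 3:
        raise ValidationError("Kruskal-Wallis needs a total of at least 3 observations")
    if _all_tied(gs):
        return GroupComparisonResult("kruskal_wallis", float("nan"), float("nan"), degenerate=True)
    if method == "chi2":
        h, p = stats.kruskal(*gs)
        return GroupComparisonResult("kruskal_wallis", float(h), float(p))
    if method != "exact":
        raise ValidationError(f"unknown method {method!r}")
    pooled = np.concatenate(gs)
    n = pooled.size
    if n > 10:
        raise ValidationError("exact Kruskal-Wallis limited to total n <= 10")
    sizes = [g.size for g in gs]
    h_obs = _kruskal_h(gs)
    count = 0
    total = 0
    # Enumerate unordered assignments of pooled observations to groups; the
    # ordering within a group does not affect H.
    def assignments(remaining: tuple, size_idx: int):
        if size_idx == len(sizes) - 1:
            yield (remaining,)
            return
        for combo in itertools.combinations(range(len(remaining)), sizes[size_idx]):
            chosen = tuple(remaining[i] for i in combo)
            rest = tuple(v for i, v in enumerate(remaining) if i not in set(combo))
            for tail in assignments(rest, size_idx + 1):
                yield (chosen, *tail)

    for split in assignments(tuple(pooled), 0):
        if _kruskal_h([np.asarray(s) for s in split]) >= h_obs - 1e-12:
            count += 1
        total += 1
    return GroupComparisonResult("kruskal_wallis", float(h_obs), count / total)


def pairwise_wilcoxon_bonferroni(
    groups, family_alpha: float = 0.05
) -> GroupComparisonResult:
    """Pairwise two-sided Wilcoxon rank-sum tests at a Bonferroni-adjusted level.

    With k groups there are m = C(k, 2) comparisons; each pair is significant
    when its p-value is below ``family_alpha / m`` (for k = 4 time points this
    is 0.05/6 ≈ 0.0083).  The exact rank-sum null distribution is used for
    combined samples of at most 20 observations without ties; otherwise the
    normal approximation with continuity and tie corrections.
    """
    gs = _as_groups(groups, min_size=1)
    k = len(gs)
    m = math.comb(k, 2)
    level = family_alpha / m
    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = gs[i], gs[j]
        combined = np.concatenate([a, b])
        has_ties = np.unique(combined).size < combined.size
        method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        pairs.append(PairResult((i, j), float(p), bool(p < level)))
    return GroupComparisonResult(
        "pairwise_wilcoxon",
        float("nan"),
        float("nan"),
        pairwise=tuple(pairs),
        adjustment="bonferroni",
        alpha=family_alpha,
        per_pair_alpha=level,
        n_comparisons=m,
    )


def decal_battery(
    normalized: pd.DataFrame,
    parametric: bool = True,
    alpha: float = 0.05,
) -> dict[str, GroupComparisonResult]:
    """Run the full comparison battery on a baseline-normalized time course.

    ``normalized`` needs columns ``time_h`` and ``value_pct`` (one row per
    case and time, as produced by ``quantify.normalize_to_baseline``).
    Groups are the distinct time points in ascending order.  Parametric
    markers get ANOVA + Welch-on-ranks + Tukey; non-parametric markers get
    Kruskal-Wallis + pairwise Wilcoxon/Bonferroni.  Both families are
    returned; ``parametric`` records which is primary.
    """
    required = {"time_h", "value_pct"}
    if not required <= set(normalized.columns):
        raise ValidationError(f"normalized table must have columns {sorted(required)}")
    times = np.sort(normalized["time_h"].unique())
    groups = [
        normalized.loc[normalized["time_h"] == t, "value_pct"].to_numpy() for t in times
    ]
    out: dict[str, GroupComparisonResult] = {
        "anova": anova_oneway(groups),
        "welch_anova_on_ranks": welch_anova_on_ranks(groups),
        "tukey_hsd": tukey_hsd(groups, alpha=alpha),
        "kruskal_wallis": kruskal_wallis(groups),
        "pairwise_wilcoxon": pairwise_wilcoxon_bonferroni(groups, family_alpha=alpha),
    }
    out["primary"] = out["tukey_hsd"] if parametric else out["pairwise_wilcoxon"]
    return out
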