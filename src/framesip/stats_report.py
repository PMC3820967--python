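"""Group-comparison statistics for the results tables.

Differences between image categories/groups are tested non-parametrically
(Kruskal-Wallis one-way ANOVA on ranks, followed by Dunn's pairwise
post-test with multiplicity adjustment); standardized differences between
two means are reported as Cohen's d; monotone associations as Spearman rank
correlations.  Dunn's z statistics are computed from the pooled mean ranks
with the usual tie correction; the default multiplicity adjustment is
Bonferroni across all pairs, with Holm as an alternative.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DunnResult",
    "kruskal_dunn",
    "cohens_d",
    "spearman_r",
    "mann_whitney",
    "significance_tier",
    "summarize_groups",
]


def significance_tier(p: float) -> str:
    """Map a p-value to the reporting tiers <0.001, <0.01, <0.05, ns."""
    if not 0.0 <= p <= 1.0 or math.isnan(p):
        raise ValueError(f"p-value out of range: {p}")
    for thr, label in ((0.001, "0.001"), (0.01, "0.01"), (0.05, "0.05")):
        if p < thr:
            return label
    return "ns"


@dataclass(frozen=True)
class DunnResult:
    """Kruskal-Wallis H test plus Dunn's pairwise post-test."""

    labels: tuple[str, ...]
    n: tuple[int, ...]
    H: float
    p: float
    pairs: tuple[tuple[str, str], ...]
    z: tuple[float, ...]
    p_raw: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    tiers: tuple[str, ...] = field(default=())

    def pairwise_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_1": [a for a, _ in self.pairs],
                "group_2": [b for _, b in self.pairs],
                "z": self.z,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "tier": self.tiers,
            }
        )


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    m = len(p_raw)
    if method == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    if method == "holm":
        order = np.argsort(p_raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"adjustment must be 'bonferroni' or 'holm', got {method!r}")


def kruskal_dunn(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    *,
    adjust: str = "bonferroni",
) -> DunnResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups with Dunn's
    pairwise post-test.

    Dunn's statistic for groups i, j compares pooled mean ranks:
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))`` with
    tie term ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided normal p-values
    are then multiplicity-adjusted across all pairs.  A fully tied pooled
    sample (H undefined) yields H = 0 and all pairs non-significant.
    """
    if isinstance(groups, dict):
        labels = tuple(groups.keys())
        samples = [np.asarray(groups[k], dtype=np.float64) for k in labels]
    else:
        samples = [np.asarray(g, dtype=np.float64) for g in groups]
        labels = tuple(f"group_{i}" for i in range(len(samples)))
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for lab, s in zip(labels, samples):
        if s.size < 2:
            raise ValueError(f"group {lab!r} has n < 2")

    pooled = np.concatenate(samples)
    N = pooled.size
    if np.ptp(pooled) == 0.0:  # every observation identical
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*samples)

    ranks = sps.rankdata(pooled)  # average ranks for ties
    sizes = [s.size for s in samples]
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs, zs, p_raw = [], [], []
    for i, j in itertools.combinations(range(len(samples)), 2):
        pairs.append((labels[i], labels[j]))
        se2 = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0.0:  # all observations tied
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
        zs.append(float(z))
        p_raw.append(float(2.0 * sps.norm.sf(abs(z))))
    p_adj = _adjust(np.asarray(p_raw), adjust)
    return DunnResult(
        labels=labels,
        n=tuple(sizes),
        H=float(H),
        p=float(p),
        pairs=tuple(pairs),
        z=tuple(zs),
        p_raw=tuple(p_raw),
        p_adjusted=tuple(float(x) for x in p_adj),
        tiers=tuple(significance_tier(x) for x in p_adj),
    )


def cohens_d(x, y) -> float:
    """Cohen's d: (mean(x) - mean(y)) / pooled SD with (n-1)-weighted pooling.

    Undefined (NaN, with a warning) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per sample")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0.0:
        warnings.warn("zero pooled SD: Cohen's d undefined", stacklevel=2)
        return math.nan
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def spearman_r(x, y, *, n_resamples: int = 9999, seed: int | None = 0) -> tuple[float, float]:
    """Spearman rank correlation with tie handling.

    For n <= 12 pairs the p-value comes from a pairings permutation test
    (exhaustive up to n = 8, otherwise ``n_resamples`` Monte-Carlo draws);
    for larger n the asymptotic t approximation is used.  Constant input
    leaves r undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("constant input: Spearman r undefined", stacklevel=2)
        return math.nan, math.nan
    if x.size <= 12:
        def statistic(perm_y):
            return sps.spearmanr(x, perm_y).statistic

        res = sps.permutation_test(
            (y,),
            statistic,
            permutation_type="pairings",
            n_resamples=math.factorial(x.size) if x.size <= 8 else n_resamples,
            alternative="two-sided",
            rng=seed,
        )
        return float(sps.spearmanr(x, y).statistic), float(res.pvalue)
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def summarize_groups(
    results: pd.DataFrame,
    *,
    measures: tuple[str, ...] = ("complexity", "self_similarity", "anisotropy"),
    by: str = "category",
    within: str = "group",
    adjust: str = "bonferroni",
) -> dict:
    """Aggregate a per-image results table into summary and significance
    grids.

    For every measure: per-(group, category) mean, SD, median and 5-95
    percentiles; and, per value of ``within`` with >= 2 levels of ``by``
    (each n >= 2), a Kruskal-Wallis + Dunn grid with Cohen's d per pair.
    Row order of the input is irrelevant.  Returns
    ``{"summary": DataFrame, "tests": {(measure, within_value): DunnResult},
    "effect_sizes": DataFrame}``.
    """
    required = {by, within, *measures}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")

    summary_rows = []
    for (g, c), sub in sorted(results.groupby([within, by]), key=lambda kv: kv[0]):
        for m in measures:
            v = sub[m].dropna().to_numpy()
            if v.size == 0:
                continue
            summary_rows.append(
                {
                    within: g,
                    by: c,
                    "measure": m,
                    "n": v.size,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                    "median": float(np.median(v)),
                    "p5": float(np.percentile(v, 5)),
                    "p95": float(np.percentile(v, 95)),
                }
            )
    summary = pd.DataFrame(summary_rows)

    tests: dict[tuple[str, str], DunnResult] = {}
    effect_rows = []
    for g, sub in sorted(results.groupby(within), key=lambda kv: kv[0]):
        samples_by_cat = {
            str(c): csub for c, csub in sub.groupby(by) if len(csub) >= 2
        }
        if len(samples_by_cat) < 2:
            warnings.warn(
                f"{within}={g!r}: fewer than two usable {by} levels; tests skipped",
                stacklevel=2,
            )
            continue
        for m in measures:
            samples = {
                c: csub[m].dropna().to_numpy() for c, csub in samples_by_cat.items()
            }
            samples = {c: v for c, v in samples.items() if v.size >= 2}
            if len(samples) < 2:
                continue
            res = kruskal_dunn(samples, adjust=adjust)
            tests[(m, str(g))] = res
            for (a, b), padj in zip(res.pairs, res.p_adjusted):
                effect_rows.append(
                    {
                        within: g,
                        "measure": m,
                        "group_1": a,
                        "group_2": b,
                        "cohens_d": cohens_d(samples[a], samples[b]),
                        "p_adjusted": padj,
                        "tier": significance_tier(padj),
                    }
                )
    return {
        "summary": summary,
        "tests": tests,
        "effect_sizes": pd.DataFrame(effect_rows),
    }
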