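"""Univariate group statistics on the MD features.

Per feature: Kruskal-Wallis across the diagnostic groups, Holm step-down
correction over the family of six features, Dunn's rank-based post-hoc test
over the six group pairs (Holm-adjusted within the feature by default), and
Hedges' g effect sizes with the small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kruskal, norm, rankdata

from .cohort import MD_FEATURES


def holm(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (monotone, bounded by Bonferroni)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    dunn_z: float
    p_raw: float
    p_adjusted: float
    hedges_g: float
    g_infinite: bool = False
    skipped: bool = False


@dataclass
class GroupComparison:
    feature: str
    kw_statistic: float
    kw_p_raw: float
    kw_p_holm: float | None = None
    pairwise: list[PairwiseResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "kw_statistic": self.kw_statistic,
            "kw_p_raw": self.kw_p_raw,
            "kw_p_holm": self.kw_p_holm,
            "pairwise": [vars(p).copy() for p in self.pairwise],
        }


def hedges_g(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Standardized mean difference with small-sample correction.

    Positive when ``a`` has the larger mean.  Returns (g, infinite_flag);
    a zero pooled SD with unequal means flags +/-inf rather than failing
    silently.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs >= 2 observations")
    df = na + nb - 2
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    diff = a.mean() - b.mean()
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    if pooled == 0:
        if diff == 0:
            return 0.0, False
        return float(np.sign(diff) * np.inf), True
    return float(correction * diff / pooled), False


def dunn_posthoc(values: np.ndarray, groups: np.ndarray,
                 adjust: str = "holm") -> list[PairwiseResult]:
    """Dunn's z over all group pairs, with tie correction.

    z_ab = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b)),
    T = sum(t^3 - t) / (12 (N - 1)) over tied groups.  Two-sided normal
    p-values, adjusted within the feature (Holm by default; "bonferroni"
    or "none" configurable).
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise ValueError("adjust must be holm, bonferroni or none")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    n_tot = len(values)
    ranks = rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    results: list[PairwiseResult] = []
    for ga, gb in combinations(names, 2):
        sel_a, sel_b = groups == ga, groups == gb
        na, nb = int(sel_a.sum()), int(sel_b.sum())
        if na == 0 or nb == 0:
            results.append(PairwiseResult(ga, gb, float("nan"), float("nan"),
                                          float("nan"), float("nan"), skipped=True))
            continue
        if var_base <= 0:  # all observations tied: no evidence either way
            z = 0.0
        else:
            z = (ranks[sel_a].mean() - ranks[sel_b].mean()) / np.sqrt(
                var_base * (1.0 / na + 1.0 / nb))
        p = float(2.0 * norm.sf(abs(z)))
        g = float("nan")
        ginf = False
        if na >= 2 and nb >= 2:
            g, ginf = hedges_g(values[sel_a], values[sel_b])
        results.append(PairwiseResult(ga, gb, float(z), p, p, g, g_infinite=ginf))

    live = [r for r in results if not r.skipped]
    raw = [r.p_raw for r in live]
    if adjust == "holm":
        adj = holm(raw)
    elif adjust == "bonferroni":
        adj = [min(1.0, p * len(raw)) for p in raw]
    else:
        adj = raw
    for r, p in zip(live, adj):
        r.p_adjusted = float(p)
    return results


def kruskal_wallis_holm(table: pd.DataFrame, features: tuple[str, ...] = MD_FEATURES,
                        group_col: str = "group",
                        dunn_adjust: str = "holm") -> list[GroupComparison]:
    """Per-feature Kruskal-Wallis with Holm correction across the family.

    Degenerate features (identical values everywhere) report H = 0 and
    p = 1 rather than raising.
    """
    names = sorted(table[group_col].unique().tolist())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    comparisons: list[GroupComparison] = []
    for feature in features:
        samples = [table.loc[table[group_col] == g, feature].dropna().to_numpy()
                   for g in names]
        if any(len(s) == 0 for s in samples):
            raise ValueError(f"feature {feature!r}: every group needs >= 1 observation")
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            comp = GroupComparison(feature, 0.0, 1.0)
        else:
            h, p = kruskal(*samples)
            comp = GroupComparison(feature, float(h), float(p))
        comp.pairwise = dunn_posthoc(
            table[feature].to_numpy(), table[group_col].to_numpy(), adjust=dunn_adjust)
        comparisons.append(comp)
    adj = holm([c.kw_p_raw for c in comparisons])
    for c, p in zip(comparisons, adj):
        c.kw_p_holm = float(p)
    return comparisons
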