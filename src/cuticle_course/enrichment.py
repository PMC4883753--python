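"""Cluster-level label statistics and categorical enrichment.

Dynamically changing trajectory clusters tend to be enriched for
arthropod-restricted genes; the comparison of mean per-cluster labeled
fractions between the "dynamic" and remaining clusters uses a two-sample
t-test (Student's by default, Welch available).  Generic over/under
representation of categories (GO-like) within clusters is tested with
exact hypergeometric tails against the clustered-gene universe, with
Benjamini-Hochberg correction within each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterModel

__all__ = [
    "ClusterLabelSummary",
    "cluster_label_fractions",
    "two_group_fraction_test",
    "category_enrichment",
]


@dataclass
class ClusterLabelSummary:
    """Per-cluster size, labeled count and labeled fraction."""

    table: pd.DataFrame  # columns: cluster, size, labeled, fraction

    def fraction(self, cluster: int) -> float:
        row = self.table[self.table["cluster"] == cluster]
        return float(row["fraction"].iloc[0])


def cluster_label_fractions(model: ClusterModel, label: Iterable[str]
                            ) -> ClusterLabelSummary:
    """Exact fraction of labeled genes in each cluster."""
    label = set(label)
    rows = []
    for c in range(1, model.k + 1):
        members = model.members(c)
        n_lab = sum(g in label for g in members)
        rows.append({"cluster": c, "size": len(members), "labeled": n_lab,
                     "fraction": n_lab / len(members) if members else float("nan")})
    return ClusterLabelSummary(pd.DataFrame(rows))


def two_group_fraction_test(summary: ClusterLabelSummary,
                            group_a: Sequence[int], group_b: Sequence[int],
                            flavor: str = "student") -> dict[str, float]:
    """Two-sample t-test comparing per-cluster labeled fractions.

    ``flavor`` selects pooled-variance Student's (default) or Welch's
    unequal-variance test; groups must be disjoint with at least 2 clusters
    each.  Returns means, t and the two-sided p.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 clusters")
    if flavor not in ("student", "welch"):
        raise ValueError(f"unknown t-test flavor: {flavor!r}")
    fa = np.array([summary.fraction(c) for c in group_a])
    fb = np.array([summary.fraction(c) for c in group_b])
    if fa.var() == 0 and fb.var() == 0 and fa.mean() == fb.mean():
        t, p = 0.0, 1.0  # degenerate identical groups; scipy yields 0/0
    else:
        t, p = stats.ttest_ind(fa, fb, equal_var=(flavor == "student"))
    return {"mean_a": float(fa.mean()), "mean_b": float(fb.mean()),
            "range_a": (float(fa.min()), float(fa.max())),
            "range_b": (float(fb.min()), float(fb.max())),
            "t": float(t), "p": float(p), "flavor": flavor}


def category_enrichment(model: ClusterModel,
                        categories: Mapping[str, Iterable[str]],
                        universe: Iterable[str] | None = None
                        ) -> pd.DataFrame:
    """Hypergeometric over/under-representation per (cluster, category).

    ``categories`` maps gene -> categories.  The universe defaults to the
    clustered genes.  For a cluster of size n with k members of a category
    of size K in a universe of N genes: over-p = P[X >= k], under-p =
    P[X <= k] for X ~ Hypergeom(N, K, n).  Benjamini-Hochberg q-values are
    computed within each cluster separately for the over and under families.
    """
    if not categories:
        raise ValueError("no categories provided")
    universe = set(universe) if universe is not None else set(model.item_ids)
    N = len(universe)
    cat_members: dict[str, set[str]] = {}
    for gene, cats in categories.items():
        if gene not in universe:
            continue
        for cat in ([cats] if isinstance(cats, str) else cats):
            cat_members.setdefault(cat, set()).add(gene)
    rows = []
    for c in range(1, model.k + 1):
        members = set(model.members(c)) & universe
        n = len(members)
        for cat in sorted(cat_members):
            K = len(cat_members[cat])
            k = len(members & cat_members[cat])
            over = float(stats.hypergeom.sf(k - 1, N, K, n))
            under = float(stats.hypergeom.cdf(k, N, K, n))
            rows.append({"cluster": c, "category": cat, "cluster_size": n,
                         "category_size": K, "overlap": k,
                         "p_over": over, "p_under": under})
    df = pd.DataFrame(rows)
    for col in ("p_over", "p_under"):
        qcol = col.replace("p_", "q_")
        df[qcol] = np.nan
        for c, grp in df.groupby("cluster"):
            df.loc[grp.index, qcol] = multipletests(grp[col], method="fdr_bh")[1]
    return df
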