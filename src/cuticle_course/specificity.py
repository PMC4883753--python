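"""Stage-specificity scoring and expression-level screens.

A gene is *expressed* when its FPKM exceeds a floor (default 1) at some time
point.  Its *specificity profile* is its per-time share of summed FPKM over
the whole course; a gene putting more than 90% of its total FPKM into one
sample is a candidate for stage-specific function (e.g. envelope deposition
for the 42 hr class).  All "greater than" comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, TimeGrid

__all__ = [
    "SpecificityProfile",
    "filter_expressed",
    "specificity_fractions",
    "count_stage_specific",
    "top_expressed_union",
    "cumulative_contributors",
    "neighbor_fold_change",
    "pair_fold",
]


@dataclass
class SpecificityProfile:
    """Per-gene per-time fraction of summed FPKM.

    Genes with zero total FPKM carry NaN fractions and are excluded from all
    counts.
    """

    gene_ids: tuple[str, ...]
    grid: TimeGrid
    fraction: np.ndarray        # (n_genes, n_times); rows sum to 1 or are NaN
    total_fpkm: np.ndarray      # (n_genes,)

    @property
    def peak_time(self) -> np.ndarray:
        """Per-gene argmax time label (NaN-total genes report the first time)."""
        idx = np.nanargmax(np.where(np.isnan(self.fraction), -1, self.fraction), axis=1)
        return np.asarray(self.grid.labels)[idx]

    @property
    def peak_fraction(self) -> np.ndarray:
        return np.nanmax(np.where(np.isnan(self.fraction), -np.inf, self.fraction), axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fraction,
                          index=pd.Index(self.gene_ids, name="gene_id"),
                          columns=list(self.grid.labels))
        df["total_fpkm"] = self.total_fpkm
        return df


def filter_expressed(matrix: ExpressionMatrix, floor: float = 1.0) -> set[str]:
    """Genes whose FPKM strictly exceeds ``floor`` at some time point."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    mask = matrix.fpkm.max(axis=1) > floor
    return {g for g, m in zip(matrix.gene_ids, mask) if m}


def specificity_fractions(matrix: ExpressionMatrix,
                          universe: Iterable[str] | None = None,
                          floor: float = 1.0) -> SpecificityProfile:
    """Per-time share of each gene's summed FPKM over the course.

    ``universe`` defaults to the expressed set at ``floor``.  Fractions are
    scale-invariant: rescaling a gene's row leaves its profile unchanged.
    """
    if universe is None:
        universe = filter_expressed(matrix, floor)
    universe = set(universe)
    unknown = universe - set(matrix.gene_ids)
    if unknown:
        raise KeyError(f"universe genes absent from matrix: {sorted(unknown)[:5]}")
    genes = tuple(g for g in matrix.gene_ids if g in universe)
    sub = matrix.subset(genes)
    total = sub.fpkm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total[:, None] > 0, sub.fpkm / total[:, None], np.nan)
    return SpecificityProfile(genes, matrix.grid, frac, total)


def count_stage_specific(profile: SpecificityProfile, alpha: float,
                         min_total_fpkm: float = 0.0
                         ) -> dict[float, list[str]]:
    """Genes whose fraction at a time point strictly exceeds ``alpha``.

    Returns ``{time: [gene, ...]}`` (genes sorted by descending fraction then
    id).  At alpha >= 0.5 each gene can appear under at most one time.  Genes
    whose total FPKM does not exceed ``min_total_fpkm`` are skipped (default
    0, i.e. only the zero-total genes are dropped).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    out: dict[float, list[str]] = {t: [] for t in profile.grid.labels}
    ok = profile.total_fpkm > min_total_fpkm if min_total_fpkm > 0 else profile.total_fpkm > 0
    for j, t in enumerate(profile.grid.labels):
        col = profile.fraction[:, j]
        hits = [(col[i], profile.gene_ids[i])
                for i in np.nonzero(ok & (np.nan_to_num(col, nan=-1.0) > alpha))[0]]
        out[t] = [g for _, g in sorted(hits, key=lambda x: (-x[0], x[1]))]
    return out


def top_expressed_union(matrix: ExpressionMatrix, n: int = 20
                        ) -> tuple[set[str], dict[float, list[str]]]:
    """Union over time points of the ``n`` most highly expressed genes.

    Ties break by descending total FPKM, then lexicographic id.  Returns the
    union and the per-time top lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n = min(n, matrix.n_genes)
    totals = dict(zip(matrix.gene_ids, matrix.fpkm.sum(axis=1)))
    per_time: dict[float, list[str]] = {}
    for j, t in enumerate(matrix.grid.labels):
        ranked = sorted(zip(matrix.gene_ids, matrix.fpkm[:, j]),
                        key=lambda x: (-x[1], -totals[x[0]], x[0]))
        per_time[t] = [g for g, _ in ranked[:n]]
    union = set().union(*per_time.values())
    return union, per_time


def cumulative_contributors(matrix: ExpressionMatrix, subset: Iterable[str],
                            share: float) -> list[str]:
    """Shortest descending-total prefix of ``subset`` exceeding ``share``.

    Genes are sorted by descending summed FPKM (ties by id); the returned
    prefix is the shortest whose cumulative total strictly exceeds ``share``
    of the subset's grand total.
    """
    if not 0 < share < 1:
        raise ValueError("share must lie in (0, 1)")
    subset = list(dict.fromkeys(subset))
    if not subset:
        raise ValueError("subset is empty")
    sub = matrix.subset(subset)
    totals = sub.fpkm.sum(axis=1)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("subset total FPKM is zero")
    order = sorted(zip(sub.gene_ids, totals), key=lambda x: (-x[1], x[0]))
    acc, prefix = 0.0, []
    for g, tot in order:
        prefix.append(g)
        acc += tot
        if acc > share * grand:
            return prefix
    return prefix


def pair_fold(a: float, b: float, pseudo: float = 0.0) -> tuple[float, str]:
    """Fold change (>= 1) and direction between two FPKM values.

    ``fold = (max + pseudo) / (min + pseudo)``.  With pseudo 0: 0 vs 0 is
    fold 1 (no change); x vs 0 is +inf, which satisfies any finite threshold.
    Direction is "rising" when b > a, "falling" when b < a, else "flat".
    """
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    hi, lo = max(a, b), min(a, b)
    if hi + pseudo == 0:
        fold = 1.0
    elif lo + pseudo == 0:
        fold = float("inf")
    else:
        fold = (hi + pseudo) / (lo + pseudo)
    direction = "rising" if b > a else ("falling" if b < a else "flat")
    return fold, direction


def neighbor_fold_change(matrix: ExpressionMatrix, pseudo: float = 0.0
                         ) -> pd.DataFrame:
    """Fold change and direction for every gene at every adjacent time pair.

    Long table with columns gene, t1, t2, fold, direction.
    """
    rows = []
    labels = matrix.grid.labels
    for i, gene in enumerate(matrix.gene_ids):
        vals = matrix.fpkm[i]
        for j, (t1, t2) in enumerate(matrix.grid.neighbor_pairs):
            fold, direction = pair_fold(vals[j], vals[j + 1], pseudo)
            rows.append((gene, t1, t2, fold, direction))
    return pd.DataFrame(rows, columns=["gene", "t1", "t2", "fold", "direction"])
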