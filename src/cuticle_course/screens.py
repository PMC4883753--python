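"""Fold-change category tables and the transcription-factor candidate screen.

The fold-category table counts, per adjacent time pair, the significant genes
(q below a cutoff) and how many of those moved more than 10-fold and more
than 100-fold (strict thresholds).  The TF screen keeps DNA-binding /
PolII-regulatory genes reaching FPKM >= 30 somewhere in the course, then
those whose expression differs at least 4-fold between some pair of
neighboring time points (inclusive thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import DEResult, ExpressionMatrix
from .specificity import pair_fold

__all__ = ["FoldCategoryTable", "fold_category_table", "tf_candidates"]


@dataclass
class FoldCategoryTable:
    """Per neighbor pair: significant-gene count and strict fold categories."""

    table: pd.DataFrame  # columns: t1, t2, n_significant, n_over_<f> per threshold
    thresholds: tuple[float, ...]

    def __post_init__(self):
        cols = [f"n_over_{format(f, 'g')}fold" for f in self.thresholds]
        for lo, hi in zip(cols, cols[1:]):
            assert (self.table[hi] <= self.table[lo]).all()
        assert (self.table[cols[0]] <= self.table["n_significant"]).all()


def fold_category_table(matrix: ExpressionMatrix, de: DEResult,
                        q_cut: float = 0.05,
                        thresholds: Sequence[float] = (10, 100)
                        ) -> FoldCategoryTable:
    """Count significant genes per adjacent pair into strict fold categories.

    A gene counts as significant when q < ``q_cut``.  Its fold is the DE
    record's when finite, otherwise recomputed from the matrix (pseudo 0, so
    an on/off gene has infinite fold and lands in every category).
    """
    thresholds = tuple(sorted(float(f) for f in thresholds))
    rows = []
    for t1, t2 in matrix.grid.neighbor_pairs:
        recs = de.for_pair(t1, t2)
        if recs.empty and not de.records.empty:
            present = set(zip(de.records["t1"], de.records["t2"]))
            if (t1, t2) not in present:
                raise ValueError(f"DE table has no records for pair {t1}/{t2}")
        sig = recs[recs["q"] < q_cut]
        folds = []
        j = matrix.grid.index(t1)
        for gene, fold in zip(sig["gene"], sig["fold"]):
            if pd.isna(fold):
                vals = matrix.row(gene)
                fold, _ = pair_fold(vals[j], vals[j + 1])
            folds.append(float(fold))
        folds = np.asarray(folds) if folds else np.empty(0)
        row = {"t1": t1, "t2": t2, "n_significant": len(sig)}
        for f in thresholds:
            row[f"n_over_{format(f, 'g')}fold"] = int((folds > f).sum())
        rows.append(row)
    return FoldCategoryTable(pd.DataFrame(rows), thresholds)


def tf_candidates(matrix: ExpressionMatrix, tf_genes: Iterable[str],
                  min_fpkm: float = 30.0, min_fold: float = 4.0
                  ) -> dict[str, object]:
    """Two-stage screen for dynamically expressed transcription factors.

    Stage 1: TF genes present in the matrix with max-over-time FPKM >=
    ``min_fpkm``.  Stage 2: of those, genes whose largest fold change between
    adjacent time points is >= ``min_fold``.  Both thresholds inclusive.
    Returns a dict with ``stage1``, ``stage2`` (sorted id lists) and
    ``max_fold`` (per stage-1 gene).
    """
    if min_fpkm <= 0 or min_fold <= 0:
        raise ValueError("thresholds must be positive")
    tf_genes = set(tf_genes)
    if not tf_genes:
        import warnings
        warnings.warn("empty TF gene list; screen returns nothing")
        return {"stage1": [], "stage2": [], "max_fold": {}}
    present = [g for g in matrix.gene_ids if g in tf_genes]
    stage1 = [g for g in present if matrix.row(g).max() >= min_fpkm]
    max_fold: dict[str, float] = {}
    for g in stage1:
        vals = matrix.row(g)
        max_fold[g] = max(pair_fold(vals[j], vals[j + 1])[0]
                          for j in range(len(vals) - 1))
    stage2 = [g for g in stage1 if max_fold[g] >= min_fold]
    return {"stage1": sorted(stage1), "stage2": sorted(stage2),
            "max_fold": max_fold}
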