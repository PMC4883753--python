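"""Isoform-fraction modeling and dominant-isoform switch detection.

A *switch* at an adjacent time pair (t, t') means the identity of a gene's
dominant isoform changes between t and t', the outgoing and incoming
dominants each clear an absolute FPKM floor at the time they dominate, and
each one's within-gene fraction moves by at least ``min_delta``.  Because
fractions are scale-free, switch calls are invariant under rescaling all
isoform FPKMs at a time point, except through the absolute floor.

Bulk "isoform change" counting is a separate, looser summary: the max fold
between any two time points per isoform, scanning all pairs, not only
neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import IsoformMatrix
from .specificity import pair_fold

__all__ = [
    "SwitchEvent",
    "isoform_fractions",
    "detect_switches",
    "count_isoform_changes",
    "trajectory_correlation",
]


@dataclass(frozen=True)
class SwitchEvent:
    """A dominant-isoform change at an adjacent time pair."""

    gene: str
    time_pair: tuple[float, float]
    isoform_up: str       # dominant after the switch
    isoform_down: str     # dominant before the switch
    frac_down_before: float
    frac_down_after: float
    frac_up_before: float
    frac_up_after: float
    min_fpkm: float       # smaller of the two dominants' FPKM when dominating


def isoform_fractions(iso: IsoformMatrix) -> pd.DataFrame:
    """Per-isoform per-time fraction of the parent gene's total FPKM.

    Times where a gene's total is zero carry NaN fractions.
    """
    gene_tot: dict[str, np.ndarray] = {}
    for i, isoform in enumerate(iso.isoform_ids):
        g = iso.parent_gene[isoform]
        gene_tot[g] = gene_tot.get(g, 0) + iso.fpkm[i]
    frac = np.empty_like(iso.fpkm)
    for i, isoform in enumerate(iso.isoform_ids):
        tot = gene_tot[iso.parent_gene[isoform]]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac[i] = np.where(tot > 0, iso.fpkm[i] / tot, np.nan)
    df = pd.DataFrame(frac, index=pd.Index(iso.isoform_ids, name="isoform_id"),
                      columns=list(iso.grid.labels))
    df.insert(0, "gene_id", [iso.parent_gene[i] for i in iso.isoform_ids])
    return df


def detect_switches(iso: IsoformMatrix, min_fpkm: float = 1.0,
                    min_delta: float = 0.25) -> list[SwitchEvent]:
    """Dominant-isoform switch events between neighboring time points.

    Deterministic given thresholds; dominance ties break toward the earlier
    isoform in the table.  Single-isoform genes never fire.
    """
    if min_fpkm < 0 or min_delta < 0:
        raise ValueError("thresholds must be >= 0")
    events: list[SwitchEvent] = []
    idx = {iso_id: i for i, iso_id in enumerate(iso.isoform_ids)}
    for gene in iso.gene_ids:
        members = iso.isoforms_of(gene)
        if len(members) < 2:
            continue
        sub = iso.fpkm[[idx[m] for m in members]]       # (m, T)
        tot = sub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, sub / tot, np.nan)
        for j, (t1, t2) in enumerate(iso.grid.neighbor_pairs):
            if tot[j] <= 0 or tot[j + 1] <= 0:
                continue
            before = int(np.argmax(sub[:, j]))
            after = int(np.argmax(sub[:, j + 1]))
            if before == after:
                continue
            if sub[before, j] < min_fpkm or sub[after, j + 1] < min_fpkm:
                continue
            d_down = frac[before, j] - frac[before, j + 1]
            d_up = frac[after, j + 1] - frac[after, j]
            if d_down < min_delta or d_up < min_delta:
                continue
            events.append(SwitchEvent(
                gene=gene, time_pair=(t1, t2),
                isoform_up=members[after], isoform_down=members[before],
                frac_down_before=float(frac[before, j]),
                frac_down_after=float(frac[before, j + 1]),
                frac_up_before=float(frac[after, j]),
                frac_up_after=float(frac[after, j + 1]),
                min_fpkm=float(min(sub[before, j], sub[after, j + 1])),
            ))
    return events


def count_isoform_changes(iso: IsoformMatrix, fold: float = 10.0,
                          pseudo: float = 0.0) -> pd.DataFrame:
    """Per-isoform max fold between any two time points, plus threshold flag.

    Columns: isoform_id, gene_id, max_fold, over_threshold.  The max scans
    all time-point pairs (equivalently max vs min over the course).
    """
    if fold < 1:
        raise ValueError("fold threshold must be >= 1")
    rows = []
    for i, isoform in enumerate(iso.isoform_ids):
        vals = iso.fpkm[i]
        f, _ = pair_fold(float(vals.max()), float(vals.min()), pseudo)
        rows.append((isoform, iso.parent_gene[isoform], f, f >= fold))
    return pd.DataFrame(rows, columns=["isoform_id", "gene_id", "max_fold",
                                       "over_threshold"])


def trajectory_correlation(iso: IsoformMatrix, a: str, b: str,
                           transform: str = "log10p1") -> float:
    """Pearson correlation of two isoform trajectories.

    Trajectories are log10(FPKM + 1)-transformed by default (``transform`` =
    "none" disables).  A constant trajectory has no defined correlation and
    returns NaN.
    """
    xa, xb = iso.row(a), iso.row(b)
    if len(xa) < 3:
        raise ValueError("need at least 3 time points")
    if transform == "log10p1":
        xa, xb = np.log10(xa + 1), np.log10(xb + 1)
    elif transform != "none":
        raise ValueError(f"unknown transform: {transform!r}")
    if np.std(xa) == 0 or np.std(xb) == 0:
        return math.nan
    return float(np.corrcoef(xa, xb)[0, 1])
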