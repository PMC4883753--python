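"""Orthogonal validation: RT-qPCR relative quantification and cuticle
thickness ratios.

qPCR expression is summarized by the comparative-Ct (delta-delta-Ct) method:
per replicate, dCt = Ct(target) - Ct(endogenous control); ddCt subtracts the
calibrator sample's mean dCt; RQ = 2^(-ddCt).  The reported RQ per sample is
2^(-mean ddCt), which makes the calibrator exactly 1 by construction, with
the spread reported as the SD of per-replicate RQs.  RQ is invariant to any
constant Ct shift applied to the whole plate.

RNA-seq expression is put on the same relative scale by dividing a gene's
per-time FPKM by its across-time mean (a "theoretical calibrator" of
averaged samples), so the relative values average to 1.

TEM cuticle-thickness comparisons use per-wing surface means and their
ratio, either thicker-over-thinner (when the section's dorsal/ventral
orientation is unknown) or in a fixed orientation, compared between
genotypes with a two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import ExpressionMatrix

__all__ = [
    "QpcrPlate",
    "ThicknessSet",
    "relative_quantification",
    "rnaseq_relative_expression",
    "thickness_ratios",
    "ratio_group_test",
]


@dataclass
class QpcrPlate:
    """Ct measurements: (sample, target, replicate) -> Ct, with an endogenous
    control gene and a calibrator sample."""

    wells: list[tuple[str, str, int, float]]  # (sample, target, replicate, Ct)
    control_gene: str
    calibrator_sample: str

    def ct(self, sample: str, target: str) -> list[float]:
        vals = [ct for s, g, _, ct in self.wells if s == sample and g == target]
        if not vals:
            raise KeyError(f"no wells for sample {sample!r}, target {target!r}")
        return vals

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for s, _, _, _ in self.wells:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def targets(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, g, _, _ in self.wells:
            if g != self.control_gene:
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class ThicknessSet:
    """Per-wing thickness measurements (nm) for two cuticle surfaces.

    ``wings`` maps wing id -> {surface name: [measurements]}; the surface
    names are conventionally "dorsal" and "ventral" (putative, for wild
    type).
    """

    wings: dict[str, dict[str, list[float]]]

    def __post_init__(self):
        for wing, surfaces in self.wings.items():
            if len(surfaces) < 2:
                raise ValueError(f"wing {wing!r} is missing a surface")
            for surf, vals in surfaces.items():
                if any(v <= 0 for v in vals):
                    raise ValueError(f"non-positive thickness in {wing}/{surf}")


def relative_quantification(plate: QpcrPlate) -> dict[str, dict[str, dict[str, float]]]:
    """Comparative-Ct RQ per target per sample.

    Returns ``{target: {sample: {"rq": ..., "sd": ...}}}``.  Replicates are
    paired with control replicates by index; the calibrator's RQ is exactly
    1.  SD is the standard deviation (ddof=1; 0 for a single replicate) of
    per-replicate RQs.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for target in plate.targets:
        # per-sample replicate dCt values
        dct: dict[str, np.ndarray] = {}
        for sample in plate.samples:
            try:
                ctrl = plate.ct(sample, plate.control_gene)
            except KeyError:
                raise ValueError(f"missing control wells for sample {sample!r}")
            try:
                tgt = plate.ct(sample, target)
            except KeyError:
                continue
            if len(tgt) != len(ctrl):
                raise ValueError(
                    f"replicate mismatch for {sample!r}/{target!r}: "
                    f"{len(tgt)} target vs {len(ctrl)} control wells")
            dct[sample] = np.asarray(tgt) - np.asarray(ctrl)
        if plate.calibrator_sample not in dct:
            raise ValueError(f"calibrator sample has no wells for {target!r}")
        cal_mean = float(dct[plate.calibrator_sample].mean())
        out[target] = {}
        for sample, values in dct.items():
            ddct = values - cal_mean
            rep_rq = 2.0 ** (-ddct)
            rq = 2.0 ** (-float(ddct.mean()))
            sd = float(np.std(rep_rq, ddof=1)) if len(rep_rq) > 1 else 0.0
            out[target][sample] = {"rq": rq, "sd": sd}
    return out


def rnaseq_relative_expression(matrix: ExpressionMatrix, gene: str
                               ) -> np.ndarray:
    """Per-time FPKM divided by the gene's across-time mean; averages to 1."""
    vals = matrix.row(gene)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError(f"gene {gene!r} has zero mean FPKM")
    return vals / mean


def thickness_ratios(thickness: ThicknessSet,
                     mode: str = "thicker_over_thinner",
                     orientation: tuple[str, str] = ("dorsal", "ventral")
                     ) -> dict[str, object]:
    """Per-wing surface-mean thickness ratios with summary mean and SD.

    ``thicker_over_thinner`` divides the larger surface mean by the smaller
    (ratios >= 1, for sections of unknown orientation); ``fixed_orientation``
    divides orientation[0] by orientation[1].
    """
    if mode not in ("thicker_over_thinner", "fixed_orientation"):
        raise ValueError(f"unknown mode: {mode!r}")
    ratios: dict[str, float] = {}
    for wing, surfaces in thickness.wings.items():
        means = {s: float(np.mean(v)) for s, v in surfaces.items()}
        if mode == "thicker_over_thinner":
            vals = sorted(means.values())
            ratios[wing] = vals[-1] / vals[0]
        else:
            top, bottom = orientation
            if top not in means or bottom not in means:
                raise ValueError(f"wing {wing!r} lacks surface {top!r} or {bottom!r}")
            ratios[wing] = means[top] / means[bottom]
    values = np.array(list(ratios.values()))
    return {
        "ratios": ratios,
        "mean": float(values.mean()),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "n": len(values),
        "mode": mode,
    }


def ratio_group_test(a: Sequence[float], b: Sequence[float],
                     flavor: str = "student") -> dict[str, float]:
    """Two-sample t-test on per-wing thickness ratios (two-sided)."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 ratios")
    if flavor not in ("student", "welch"):
        raise ValueError(f"unknown t-test flavor: {flavor!r}")
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=(flavor == "student"))
    return {"t": float(t), "p": float(p),
            "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
            "flavor": flavor}
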