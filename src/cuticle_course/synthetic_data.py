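"""Seeded generators emulating the statistical structure of the wing
cuticle-deposition time course, so every analysis stage is testable without
any download.

What is emulated
----------------
* seven ordered conditions (42-96 hr awp by default) of non-negative FPKM;
* planted trajectory archetypes: a single-stage spike (> 90% of total FPKM
  at one time point), monotone rise, monotone fall, flat housekeeping and
  bimodal (early + late peaks);
* multiplicative log-normal noise whose squared coefficient of variation
  decreases with expression level, CV^2(FPKM) = a / FPKM + b;
* dominant-isoform switches planted at named adjacent time pairs;
* protein sequences with planted compositional biases (absent residues,
  single residues above 20% or 30%, short length), realized by exact count
  construction so the planted truth always holds;
* per-wing dorsal/ventral thickness ratios drawn from stated group normals
  (wild type 1.2 +/- 0.11; perturbed 2.1 +/- 0.43);
* qPCR plates built by inverting the comparative-Ct model from chosen true
  RQ values.

Every generator is bit-reproducible under a fixed seed and configuration,
and every planted truth round-trips through its analysis operation at zero
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_model import (DEFAULT_GRID, STANDARD_AA, ExpressionMatrix,
                       IsoformMatrix, ProteinSet, TimeGrid)
from .validation import QpcrPlate, ThicknessSet

__all__ = [
    "SimConfig",
    "NoisePlan",
    "IsoformPlan",
    "ProteinSpec",
    "ProteinPlan",
    "ThicknessPlan",
    "QpcrPlan",
    "PlantedSwitch",
    "ARCHETYPES",
    "simulate_timecourse",
    "simulate_isoforms",
    "simulate_proteins",
    "simulate_thickness",
    "simulate_qpcr",
]

ARCHETYPES = ("spike", "rise", "fall", "flat", "bimodal")


@dataclass(frozen=True)
class NoisePlan:
    """Multiplicative log-normal noise with CV^2(x) = a / x + b.

    Defaults give CV^2 = 1.0 at FPKM 1, 0.105 at FPKM 10 and 0.015 at FPKM
    100 — high variability for barely detected genes, a few percent for
    abundant ones, echoing the decreasing cross-replicate CV^2 trend of
    duplicate RNA-seq libraries.
    """

    a: float = 1.0
    b: float = 0.005

    def cv2(self, x: np.ndarray) -> np.ndarray:
        return self.a / np.maximum(x, 1e-9) + self.b

    def sigma(self, x: np.ndarray) -> np.ndarray:
        """Log-normal shape parameter giving the requested CV^2."""
        return np.sqrt(np.log1p(self.cv2(x)))


@dataclass(frozen=True)
class IsoformPlan:
    """Plan for the isoform table: gene count, isoforms per gene, switches.

    ``n_switches`` genes receive a planted dominant-isoform swap
    (major fraction ``dom_frac`` -> ``1 - dom_frac``) at an adjacent pair,
    assigned round-robin over ``switch_pairs`` (grid indices of the earlier
    time; the default plants switches in the three earliest pairs, where
    real switching concentrates).  The dominance margin ``dom_frac`` minus
    its complement is the documented separation for detection.
    """

    n_genes: int = 100
    isoforms_per_gene: int = 2
    n_switches: int = 20
    switch_pairs: tuple[int, ...] = (0, 1, 2)
    dom_frac: float = 0.8
    gene_log_mean: float = math.log(50.0)
    gene_log_sd: float = 0.5
    noise_sigma: float = 0.1


@dataclass(frozen=True)
class ProteinSpec:
    """One planted protein: length, banned residues, enriched residues."""

    length: int
    absent: tuple[str, ...] = ()
    high: tuple[tuple[str, float], ...] = ()  # (residue, target fraction)


def _default_protein_specs() -> tuple[ProteinSpec, ...]:
    """Twenty candidate-like proteins: 10 short, 9 Trp-free, assorted
    single-residue enrichments (2x >20% Ala, 1x >20% Val, 1x >20% His,
    1x >30% Gly) and scattered other absences."""
    specs = []
    for i in range(20):
        length = 110 + 9 * i if i < 10 else 230 + 31 * (i - 10)
        absent: list[str] = []
        high: list[tuple[str, float]] = []
        if i < 9:
            absent.append("W")
        if i in (3, 4, 5, 6, 12):
            absent.append("N")
        if i in (5, 6, 13, 14):
            absent.append("D")
        if i in (0, 10):
            high.append(("A", 0.22))
        if i == 1:
            high.append(("V", 0.22))
        if i == 2:
            high.append(("H", 0.22))
        if i == 11:
            high.append(("G", 0.32))
        specs.append(ProteinSpec(length, tuple(absent), tuple(high)))
    return tuple(specs)


@dataclass(frozen=True)
class ProteinPlan:
    specs: tuple[ProteinSpec, ...] = field(default_factory=_default_protein_specs)


@dataclass(frozen=True)
class ThicknessPlan:
    """Group ratio normals; defaults are the wild-type and knockdown wing
    dorsal/ventral procuticle values (means 1.2 and 2.1, SDs 0.11 and
    0.43)."""

    groups: tuple[tuple[str, float, float], ...] = (
        ("wild_type", 1.2, 0.11),
        ("knockdown", 2.1, 0.43),
    )
    n_wings: int = 8
    n_measurements: int = 10
    base_thickness: float = 1000.0  # nm, thinner surface
    jitter: float = 0.02            # measurement CV around the surface mean


@dataclass(frozen=True)
class QpcrPlan:
    n_replicates: int = 3
    control_ct: float = 20.0
    base_dct: float = 2.0
    noise_sd: float = 0.1  # cycles


@dataclass(frozen=True)
class SimConfig:
    """Everything the generators need; identical seed + config => identical
    outputs."""

    seed: int = 0
    n_genes: int = 500
    grid: TimeGrid = DEFAULT_GRID
    archetype_mix: tuple[tuple[str, float], ...] = (
        ("spike", 0.2), ("rise", 0.2), ("fall", 0.2),
        ("flat", 0.2), ("bimodal", 0.2),
    )
    #: total-FPKM log-normal; the default keeps planted genes well above the
    #: noise floor so archetypes stay separable (the documented separation)
    expression_log_mean: float = math.log(300.0)
    expression_log_sd: float = 0.8
    spike_peak_fraction: float = 0.97
    spike_time_index: int = 0
    noise: NoisePlan = NoisePlan()
    noise_scale: float = 1.0  # multiplies the noise sigma; 0 = noiseless
    n_replicates: int = 2
    isoforms: IsoformPlan = IsoformPlan()
    proteins: ProteinPlan = ProteinPlan()
    thickness: ThicknessPlan = ThicknessPlan()
    qpcr: QpcrPlan = QpcrPlan()

    def __post_init__(self):
        total = sum(p for _, p in self.archetype_mix)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"archetype proportions sum to {total}, not 1")
        if any(name not in ARCHETYPES for name, _ in self.archetype_mix):
            raise ValueError("unknown archetype in mix")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class PlantedSwitch:
    gene: str
    time_pair: tuple[float, float]
    isoform_down: str
    isoform_up: str


def _archetype_profile(name: str, config: SimConfig) -> np.ndarray:
    T = len(config.grid)
    if name == "spike":
        peak = config.spike_peak_fraction
        p = np.full(T, (1 - peak) / (T - 1))
        p[config.spike_time_index] = peak
    elif name == "rise":
        p = 2.0 ** np.arange(T)
    elif name == "fall":
        p = 2.0 ** np.arange(T)[::-1].astype(float)
    elif name == "flat":
        p = np.ones(T)
    elif name == "bimodal":
        p = np.full(T, 0.1 / (T - 2))
        p[0] = p[-1] = 0.45
    else:
        raise ValueError(f"unknown archetype: {name!r}")
    return p / p.sum()


def simulate_timecourse(config: SimConfig
                        ) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Planted-archetype FPKM matrix with ground-truth labels.

    Returns the matrix (with a replicate table attached, merged values being
    replicate means) and a gene -> archetype map.  With ``noise_scale`` 0
    the matrix holds the exact noiseless archetype values.
    """
    rng = config.rng(1)
    T = len(config.grid)
    counts: list[tuple[str, int]] = []
    assigned = 0
    for i, (name, prop) in enumerate(config.archetype_mix):
        n = (config.n_genes - assigned if i == len(config.archetype_mix) - 1
             else int(round(prop * config.n_genes)))
        counts.append((name, n))
        assigned += n
    gene_ids, labels, clean_rows = [], {}, []
    g = 0
    for name, n in counts:
        profile = _archetype_profile(name, config)
        for _ in range(n):
            total = float(rng.lognormal(config.expression_log_mean,
                                        config.expression_log_sd))
            gene = f"G{g:05d}_{name}"
            gene_ids.append(gene)
            labels[gene] = name
            clean_rows.append(total * profile)
            g += 1
    clean = np.asarray(clean_rows)
    if config.noise_scale == 0:
        reps = np.repeat(clean[:, :, None], config.n_replicates, axis=2)
        merged = clean.copy()
    else:
        sigma = config.noise.sigma(clean) * config.noise_scale
        z = rng.standard_normal((len(gene_ids), T, config.n_replicates))
        # mean-one log-normal factors: E[exp(sigma Z - sigma^2/2)] = 1
        reps = clean[:, :, None] * np.exp(
            sigma[:, :, None] * z - 0.5 * sigma[:, :, None] ** 2)
        merged = reps.mean(axis=2)
    matrix = ExpressionMatrix(tuple(gene_ids), config.grid, merged,
                              replicate_fpkm=reps)
    return matrix, labels


def simulate_isoforms(config: SimConfig
                      ) -> tuple[IsoformMatrix, list[PlantedSwitch]]:
    """Isoform table with planted dominant-isoform switches.

    Switching genes carry the major isoform at ``dom_frac`` before the
    planted pair and at ``1 - dom_frac`` after it (the minor isoform
    mirrored); non-switching genes keep stable fractions.  The planted
    events are returned as ground truth.
    """
    plan = config.isoforms
    n_pairs = len(config.grid) - 1
    for p in plan.switch_pairs:
        if not 0 <= p < n_pairs:
            raise ValueError(f"switch pair index {p} is not an adjacent pair "
                             f"of the grid (0..{n_pairs - 1})")
    if plan.n_switches > plan.n_genes:
        raise ValueError("more switches than genes")
    rng = config.rng(2)
    T = len(config.grid)
    m = plan.isoforms_per_gene
    iso_ids, parent, rows = [], {}, []
    planted: list[PlantedSwitch] = []
    minor = (1 - plan.dom_frac) / (m - 1)
    for gi in range(plan.n_genes):
        gene = f"SG{gi:04d}"
        names = [f"{gene}-R{chr(ord('A') + k)}" for k in range(m)]
        total = float(rng.lognormal(plan.gene_log_mean, plan.gene_log_sd))
        frac = np.full((m, T), minor)
        if gi < plan.n_switches:
            pair_idx = plan.switch_pairs[gi % len(plan.switch_pairs)]
            frac[0, :pair_idx + 1] = plan.dom_frac
            frac[1, :pair_idx + 1] = minor
            frac[1, pair_idx + 1:] = plan.dom_frac
            frac[0, pair_idx + 1:] = minor
            planted.append(PlantedSwitch(
                gene,
                (config.grid.labels[pair_idx], config.grid.labels[pair_idx + 1]),
                names[0], names[1]))
        else:
            frac[0, :] = plan.dom_frac
        fpkm = total * frac
        if plan.noise_sigma > 0:
            fpkm = fpkm * rng.lognormal(0.0, plan.noise_sigma, size=fpkm.shape)
        for k, name in enumerate(names):
            iso_ids.append(name)
            parent[name] = gene
            rows.append(fpkm[k])
    return IsoformMatrix(tuple(iso_ids), parent, config.grid,
                         np.asarray(rows)), planted


def simulate_proteins(config: SimConfig
                      ) -> tuple[ProteinSet, dict[str, dict[str, object]]]:
    """Protein set realizing the planted compositional biases exactly.

    Residue counts are constructed (not sampled), so banned residues are
    truly absent and enriched residues clear their target fraction; only the
    residue order is randomized.  Returns the set and per-protein truth
    (length, absent set, enriched residues).
    """
    rng = config.rng(3)
    records: dict[str, str] = {}
    truth: dict[str, dict[str, object]] = {}
    for i, spec in enumerate(config.proteins.specs):
        pid = f"prot{i:03d}"
        absent = set(spec.absent)
        for res, frac in spec.high:
            if res in absent:
                raise ValueError(
                    f"{pid}: residue {res} cannot be both absent and enriched")
            if not 0 < frac < 1:
                raise ValueError(f"{pid}: infeasible target fraction {frac}")
        L = spec.length
        counts = {a: 0 for a in STANDARD_AA}
        used = 0
        for res, frac in spec.high:
            counts[res] = int(math.ceil(frac * L)) + 1
            used += counts[res]
        if used > L:
            raise ValueError(f"{pid}: enriched residues exceed the length")
        background = [a for a in STANDARD_AA
                      if a not in absent and counts[a] == 0]
        remaining = L - used
        for j, a in enumerate(background):
            share = remaining // len(background) + (1 if j < remaining % len(background) else 0)
            counts[a] = share
        letters = [a for a, c in counts.items() for _ in range(c)]
        rng.shuffle(letters)
        records[pid] = "".join(letters)
        truth[pid] = {
            "length": L,
            "absent": frozenset(absent),
            "high": {res: frac for res, frac in spec.high},
            "short": L < 200,
        }
    return ProteinSet(records), truth


def simulate_thickness(config: SimConfig
                       ) -> dict[str, tuple[ThicknessSet, dict[str, float]]]:
    """Per-group wing thickness measurements realizing drawn ratios.

    Each wing's ratio is drawn from the group's normal (redrawn on the rare
    draw <= 1 so thicker-over-thinner recovers it); the thin surface sits at
    the base thickness and the thick surface at base x ratio, with
    multiplicative measurement jitter.  At jitter 0 the ratios round-trip
    exactly.  Returns ``{group: (ThicknessSet, drawn per-wing ratios)}``.
    """
    plan = config.thickness
    if plan.base_thickness <= 0 or any(m <= 0 for _, m, _ in plan.groups):
        raise ValueError("means must be positive")
    rng = config.rng(4)
    out: dict[str, tuple[ThicknessSet, dict[str, float]]] = {}
    for group, mean, sd in plan.groups:
        wings: dict[str, dict[str, list[float]]] = {}
        drawn: dict[str, float] = {}
        for w in range(plan.n_wings):
            ratio = float(rng.normal(mean, sd))
            while ratio <= 1.0:
                ratio = float(rng.normal(mean, sd))
            wing = f"{group}_wing{w}"
            drawn[wing] = ratio
            thin = plan.base_thickness
            thick = plan.base_thickness * ratio
            if plan.jitter > 0:
                jit = rng.normal(1.0, plan.jitter,
                                 size=(2, plan.n_measurements))
            else:
                jit = np.ones((2, plan.n_measurements))
            wings[wing] = {
                "dorsal": list(thick * jit[0]),
                "ventral": list(thin * jit[1]),
            }
        out[group] = (ThicknessSet(wings), drawn)
    return out


def simulate_qpcr(config: SimConfig, true_rq: dict[str, float],
                  target: str = "target", control: str = "Xbp1",
                  calibrator: str = "calibrator") -> QpcrPlate:
    """Invert the comparative-Ct model: build a plate whose RQ analysis
    recovers ``true_rq`` up to replicate noise.

    ``true_rq`` maps sample -> RQ and must give the calibrator sample the
    value 1.  The control gene sits at a constant Ct; target Ct is offset by
    the base dCt minus log2(RQ), plus per-well normal noise in cycles.
    """
    plan = config.qpcr
    if calibrator not in true_rq:
        true_rq = {calibrator: 1.0, **true_rq}
    if not math.isclose(true_rq[calibrator], 1.0, abs_tol=1e-12):
        raise ValueError("the calibrator's true RQ must be 1")
    if any(v <= 0 for v in true_rq.values()):
        raise ValueError("true RQ values must be positive")
    rng = config.rng(5)
    wells: list[tuple[str, str, int, float]] = []
    for sample, rq in true_rq.items():
        for rep in range(plan.n_replicates):
            ctrl_ct = plan.control_ct + (rng.normal(0, plan.noise_sd)
                                         if plan.noise_sd > 0 else 0.0)
            tgt_ct = (ctrl_ct + plan.base_dct - math.log2(rq)
                      + (rng.normal(0, plan.noise_sd) if plan.noise_sd > 0 else 0.0))
            wells.append((sample, control, rep, ctrl_ct))
            wells.append((sample, target, rep, tgt_ct))
    return QpcrPlate(wells, control_gene=control, calibrator_sample=calibrator)
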