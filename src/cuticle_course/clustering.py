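"""Jensen-Shannon distances, sample dendrograms and PAM trajectory clustering.

Expression profiles (a sample's column over genes, or a gene's trajectory
over time) are normalized to probability vectors; their pairwise
Jensen-Shannon distance — the square root of the Jensen-Shannon divergence —
is a metric bounded by 1 when logarithms are taken base 2.  Samples are
related by agglomerative clustering of their JS distances; gene trajectories
are partitioned with a deterministic PAM (partitioning around medoids):
greedy BUILD initialization followed by steepest-descent SWAP, ties broken by
lowest item index.  Cluster quality is summarized by silhouettes,
s = (b - a) / max(a, b), with singleton clusters scoring 0.

The log10(FPKM + 1) transform seen on trajectory plots is a display
convention only; distances always use the probability-normalized profiles,
which makes cluster assignment invariant under per-gene rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_model import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterModel",
    "to_probability_profile",
    "js_distance",
    "sample_distance_matrix",
    "gene_trajectory_distances",
    "build_dendrogram",
    "pam",
    "silhouette",
]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal distance matrix over named items."""

    item_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        self.item_ids = tuple(str(i) for i in self.item_ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.item_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.item_ids)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples, heights in JS-distance units."""

    item_ids: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy hierarchy format
    method: str

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.item_ids[node.id]
            left, right = node.get_left(), node.get_right()
            bl = node.dist - left.dist
            br = node.dist - right.dist
            return f"({walk(left)}:{bl:.6g},{walk(right)}:{br:.6g})"

        return walk(tree) + ";"


@dataclass
class ClusterModel:
    """PAM output: assignment, medoids, cost and silhouettes."""

    k: int
    item_ids: tuple[str, ...]
    assignment: dict[str, int]          # item -> cluster id in 1..k
    medoids: tuple[str, ...]            # one per cluster, index = cluster-1
    total_cost: float
    silhouettes: dict[str, float] = field(default_factory=dict)
    cluster_silhouette: dict[int, float] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return [g for g in self.item_ids if self.assignment[g] == cluster]

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes = {c: 0 for c in range(1, self.k + 1)}
        for c in self.assignment.values():
            sizes[c] += 1
        return sizes


def to_probability_profile(values: Sequence[float]) -> np.ndarray:
    """Normalize a non-negative vector to sum 1."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative entries")
    s = v.sum()
    if s <= 0:
        raise ValueError("all-zero vector has no probability profile")
    return v / s


def js_distance(p: Sequence[float], q: Sequence[float], base: float = 2.0) -> float:
    """Jensen-Shannon distance between two probability vectors.

    sqrt of the JS divergence; with base-2 logs the result lies in [0, 1]
    and satisfies the metric axioms.  The convention 0 * log 0 = 0 applies.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * (np.log(a[mask] / b[mask]) / np.log(base))))

    jsd = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    return float(np.sqrt(max(jsd, 0.0)))


def sample_distance_matrix(matrix: ExpressionMatrix, base: float = 2.0
                           ) -> DistanceMatrix:
    """Pairwise JS distances between time points (columns over genes)."""
    sums = matrix.fpkm.sum(axis=0)
    if (sums <= 0).any():
        bad = matrix.grid.labels[int(np.argmax(sums <= 0))]
        raise ValueError(f"time point {bad} has zero total FPKM")
    profiles = matrix.fpkm / sums
    n = len(matrix.grid)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = js_distance(profiles[:, i], profiles[:, j], base)
    labels = tuple(format(t, "g") for t in matrix.grid.labels)
    return DistanceMatrix(labels, d)


def gene_trajectory_distances(matrix: ExpressionMatrix,
                              genes: Iterable[str] | None = None,
                              base: float = 2.0) -> DistanceMatrix:
    """Pairwise JS distances between probability-normalized gene trajectories."""
    genes = tuple(genes) if genes is not None else matrix.gene_ids
    sub = matrix.subset(genes)
    totals = sub.fpkm.sum(axis=1)
    if (totals <= 0).any():
        bad = sub.gene_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"gene {bad} has zero total FPKM")
    profiles = sub.fpkm / totals[:, None]
    n = len(sub.gene_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = js_distance(profiles[i], profiles[j], base)
    return DistanceMatrix(sub.gene_ids, d)


def build_dendrogram(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    if len(dist) < 2:
        raise ValueError("need at least 2 items")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage: {linkage!r}")
    Z = hierarchy.linkage(squareform(dist.d, checks=False), method=linkage)
    return Dendrogram(dist.item_ids, Z, linkage)


def _assign(d: np.ndarray, medoids: list[int]) -> np.ndarray:
    """Nearest-medoid labels (positions into ``medoids``); ties -> lowest
    medoid index, except that a medoid always belongs to its own cluster."""
    sub = d[:, medoids]                       # (n, k)
    labels = np.argmin(sub, axis=1)           # argmin takes first minimum
    for pos, m in enumerate(medoids):
        labels[m] = pos
    return labels


def pam(dist: DistanceMatrix, k: int, exhaustive_max_items: int = 12
        ) -> ClusterModel:
    """Deterministic PAM: greedy BUILD then steepest-descent SWAP.

    BUILD seeds the medoid set with the item minimizing total distance and
    then repeatedly adds the item with the largest cost reduction.  SWAP
    evaluates every (medoid, non-medoid) exchange and applies the single best
    strictly-improving one until a local optimum; all ties break toward the
    lowest item index, so the result is reproducible without a seed.

    Instances of at most ``exhaustive_max_items`` items are solved exactly by
    enumerating every medoid subset (single-swap descent can stall on
    equal-cost plateaus that tiny instances make likely); ties take the
    lexicographically smallest medoid set.
    """
    n = len(dist)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    d = dist.d

    if n <= exhaustive_max_items:
        import itertools
        best_meds, best_cost = None, np.inf
        for meds in itertools.combinations(range(n), k):
            c = float(d[:, meds].min(axis=1).sum())
            if c < best_cost - 1e-12:
                best_meds, best_cost = list(meds), c
        return _finalize(dist, d, k, best_meds)

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        best_gain, best_item = -np.inf, None
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(nearest - d[:, c], 0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_item = gain, c
        medoids.append(best_item)
        nearest = np.minimum(nearest, d[:, best_item])

    def cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)  # (delta, medoid position, candidate)
        for mi in range(k):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                delta = cost(trial) - current
                if delta < best[0] - 1e-12:
                    best = (delta, mi, c)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            current += best[0]
            improved = True

    return _finalize(dist, d, k, medoids)


def _finalize(dist: DistanceMatrix, d: np.ndarray, k: int,
              medoids: list[int]) -> ClusterModel:
    # canonical cluster numbering: medoids sorted by item index
    medoids = sorted(medoids)
    labels = _assign(d, medoids)
    assignment = {dist.item_ids[i]: int(labels[i]) + 1
                  for i in range(len(dist))}
    model = ClusterModel(
        k=k,
        item_ids=dist.item_ids,
        assignment=assignment,
        medoids=tuple(dist.item_ids[m] for m in medoids),
        total_cost=float(d[:, medoids].min(axis=1).sum()),
    )
    if k >= 2:
        sil, csil = silhouette(model, dist)
        model.silhouettes = sil
        model.cluster_silhouette = csil
    return model


def silhouette(model: ClusterModel, dist: DistanceMatrix
               ) -> tuple[dict[str, float], dict[int, float]]:
    """Per-item and per-cluster-mean silhouettes, s = (b-a)/max(a,b).

    Items in singleton clusters score 0; so does an item with a = b = 0.
    """
    if model.k < 2:
        raise ValueError("silhouette needs k >= 2")
    idx = {g: i for i, g in enumerate(dist.item_ids)}
    members = {c: [idx[g] for g in model.members(c)] for c in range(1, model.k + 1)}
    per_item: dict[str, float] = {}
    for g in model.item_ids:
        i = idx[g]
        c = model.assignment[g]
        own = [j for j in members[c] if j != i]
        if not own:
            per_item[g] = 0.0
            continue
        a = float(dist.d[i, own].mean())
        b = min(float(dist.d[i, members[o]].mean())
                for o in members if o != c and members[o])
        per_item[g] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    per_cluster = {
        c: (float(np.mean([per_item[g] for g in model.members(c)]))
            if members[c] else float("nan"))
        for c in range(1, model.k + 1)
    }
    return per_item, per_cluster
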