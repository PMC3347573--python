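"""Between-population structure: Nei distance, UPGMA trees, and MDS.

Nei's standard genetic distance between populations X and Y over a set of
shared loci is ``D = -ln I`` with the normalized identity
``I = J_XY / sqrt(J_X J_Y)``, where ``J_XY = sum_l sum_i p_i q_i``,
``J_X = sum_l sum_i p_i^2`` and ``J_Y = sum_l sum_i q_i^2`` (sums over loci
of per-allele products, normalized over the locus count implicitly through
the ratio).  Populations sharing no alleles anywhere have ``I = 0`` and an
infinite distance, which is flagged rather than silently propagated.

UPGMA agglomerates the closest pair of clusters, with the inter-cluster
distance being the unweighted (size-weighted over members) average of
pairwise distances; node height is half the merge distance, so the tree is
ultrametric by construction.  Ties break on the lowest-index pair in the
current cluster ordering, making trees reproducible.

Classical (principal-coordinate) multidimensional scaling is the default
ordination; an optional metric stress-majorization refinement (SMACOF)
starts from the classical solution with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .strdata import AlleleFrequencyTable

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Ordination",
    "nei_distance",
    "nei_distance_matrix",
    "upgma",
    "mds",
    "write_phylip_distances",
    "read_phylip_distances",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over ordered population ids."""

    ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.diag(v) == 0.0):
            raise ValueError("distance diagonal must be 0")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0:
                raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def has_infinite(self) -> bool:
        return bool(np.isinf(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class TreeNode:
    """Rooted ultrametric tree node; leaves carry population ids."""

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out += c.leaves()
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"

    def cophenetic(self) -> DistanceMatrix:
        """Leaf-pair distances implied by the tree (2 x merge height)."""
        ids = self.leaves()
        index = {name: i for i, name in enumerate(ids)}
        n = len(ids)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[int]:
            if node.is_leaf:
                return [index[node.name or ""]]
            groups = [walk(c) for c in node.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            d[i, j] = d[j, i] = 2.0 * node.height
            return [i for g in groups for i in g]

        walk(self)
        return DistanceMatrix(ids, d, metric="cophenetic")

    def check_ultrametric(self, tol: float = 1e-9) -> None:
        def depth(node: TreeNode) -> list[float]:
            if node.is_leaf:
                return [node.height]
            return [h for c in node.children for h in depth(c)]

        root_to_leaf = [self.height - h for h in depth(self)]
        if max(root_to_leaf) - min(root_to_leaf) > tol:
            raise AssertionError("tree is not ultrametric")


@dataclass
class Ordination:
    """Low-dimensional embedding of a distance matrix."""

    ids: list[str]
    coords: np.ndarray  # (n, dims), centered at the origin
    stress: float
    algorithm: str
    dropped_variance: float = 0.0  # share of |eigenvalue| mass discarded

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.ids, columns=cols)


# ---------------------------------------------------------------------------
# Nei standard distance
# ---------------------------------------------------------------------------

def nei_distance(
    freqs_x: Mapping[str, Mapping[int, float]],
    freqs_y: Mapping[str, Mapping[int, float]],
) -> float:
    """Nei (standard) distance from per-locus allele-frequency maps.

    Arguments map locus name -> {allele: frequency}; only loci present in
    both populations enter.  Returns ``inf`` when the populations share no
    alleles at any locus.
    """
    shared = [l for l in freqs_x if l in freqs_y and freqs_x[l] and freqs_y[l]]
    if not shared:
        raise ValueError("no shared loci")
    jxy = jx = jy = 0.0
    for l in shared:
        fx, fy = freqs_x[l], freqs_y[l]
        jx += sum(p * p for p in fx.values())
        jy += sum(q * q for q in fy.values())
        jxy += sum(p * fy.get(a, 0.0) for a, p in fx.items())
    i = jxy / np.sqrt(jx * jy)
    if i <= 0.0:
        return float("inf")
    return float(-np.log(min(i, 1.0)))


def nei_distance_matrix(
    aft: AlleleFrequencyTable, populations: Sequence[str] | None = None
) -> DistanceMatrix:
    pops = list(populations) if populations is not None else aft.populations()
    maps = {p: {l: aft.freqs(p, l) for l in aft.loci(p)} for p in pops}
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(maps[pops[i]], maps[pops[j]])
    return DistanceMatrix(pops, d, metric="nei")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into an ultrametric rooted tree.

    Cluster-pair distance is the mean over all member pairs (UPGMA); merges
    pick the smallest distance, breaking ties on the lowest-index pair in
    the current cluster ordering.  Node height is half the merge distance.
    """
    if dm.has_infinite or np.isnan(dm.values).any():
        raise ValueError("UPGMA requires finite distances")
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name=pid, height=0.0) for pid in dm.ids]
    sizes = [1] * n
    d = dm.values.astype(float).copy()
    active = list(range(n))
    store: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                val = d[i, j]
                if best is None or val < best[0]:
                    best = (val, ai, aj)
        dist, ai, aj = best  # type: ignore[misc]
        i, j = active[ai], active[aj]
        merged = TreeNode(height=dist / 2.0, children=[store[i], store[j]])
        new_size = sizes[i] + sizes[j]
        # size-weighted average distance to every other active cluster
        for a in active:
            if a in (i, j):
                continue
            d_new = (sizes[i] * d[i, a] + sizes[j] * d[j, a]) / new_size
            d[i, a] = d[a, i] = d_new
        sizes[i] = new_size
        store[i] = merged
        active.pop(aj)
    root = store[active[0]]
    root.check_ultrametric(tol=1e-6)
    return root


# ---------------------------------------------------------------------------
# Multidimensional scaling
# ---------------------------------------------------------------------------

def _stress(coords: np.ndarray, d: np.ndarray) -> float:
    from scipy.spatial.distance import pdist, squareform

    dd = squareform(pdist(coords))
    num = float(np.sum((dd - d) ** 2))
    den = float(np.sum(d**2))
    return np.sqrt(num / den) if den > 0 else 0.0


def mds(
    dm: DistanceMatrix,
    dims: int = 2,
    algorithm: str = "classical",
    seed: int = 0,
) -> Ordination:
    """Embed a distance matrix in ``dims`` dimensions.

    ``'classical'`` is principal-coordinate analysis: double-center the
    squared distances, eigendecompose, keep the top positive eigenvalues
    (negative ones — non-Euclidean input — are dropped and their share of
    absolute eigenvalue mass reported).  ``'stress-majorization'`` refines
    that solution with metric SMACOF (fixed seed).  Stress is Kruskal's
    stress-1 against the input distances.
    """
    d = dm.values
    n = d.shape[0]
    if dims >= n:
        raise ValueError("dims must be < number of populations")
    if not np.isfinite(d).all():
        raise ValueError("MDS requires finite distances")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals[:dims], 0.0, None)
    if evals[0] > 0:  # numerically-zero eigenvalues would inject noise axes
        pos[pos < evals[0] * 1e-12] = 0.0
    coords = evecs[:, :dims] * np.sqrt(pos)
    total_abs = float(np.abs(evals).sum())
    dropped = float(np.abs(evals[evals < 0]).sum()) / total_abs if total_abs > 0 else 0.0
    coords -= coords.mean(axis=0, keepdims=True)

    if algorithm == "classical":
        return Ordination(list(dm.ids), coords, _stress(coords, d), "classical", dropped)
    if algorithm == "stress-majorization":
        from sklearn.manifold import smacof

        coords2, _ = smacof(
            d,
            n_components=dims,
            init=coords,
            n_init=1,
            metric=True,
            random_state=seed,
            normalized_stress=False,
        )
        coords2 -= coords2.mean(axis=0, keepdims=True)
        return Ordination(
            list(dm.ids), coords2, _stress(coords2, d), "stress-majorization", dropped
        )
    raise ValueError(f"unknown MDS algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# PHYLIP-style distance I/O
# ---------------------------------------------------------------------------

def write_phylip_distances(dm: DistanceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, pid in enumerate(dm.ids):
            row = " ".join(f"{x:.10f}" for x in dm.values[i])
            fh.write(f"{pid[:10]:<10} {row}\n")


def read_phylip_distances(path) -> DistanceMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    n = int(lines[0].strip())
    ids = []
    rows = []
    for line in lines[1 : n + 1]:
        parts = line.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(ids, np.asarray(rows), metric="phylip")
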