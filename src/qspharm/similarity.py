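"""Distance metrics, pairwise distance matrices, and hierarchical clustering.

Drugs are compared two ways: by chemistry, via the Tanimoto distance
``1 - |a&b| / |a|b|`` between 2D structure bit fingerprints, and by
pharmacology, via the cosine distance ``1 - (d_i . d_j)/(|d_i||d_j|)``
between binary target vectors (one row of the interaction matrix per drug).
Targets are compared by the same cosine distance applied to the transposed
matrix (per-target ligand vectors). Dendrograms are built by agglomerative
clustering with a deterministic lexicographic tie-break so that runs are
reproducible even on degenerate distance data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import AnalysisError, ValidationError

LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary fingerprint stored as its set of on-bit positions."""

    length: int
    on_bits: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "on_bits", frozenset(self.on_bits))
        if any(not (0 <= b < self.length) for b in self.on_bits):
            raise ValidationError("fingerprint bit position outside [0, length)")

    @classmethod
    def from_bitstring(cls, bits: str) -> "BitFingerprint":
        return cls(len(bits), frozenset(i for i, c in enumerate(bits) if c == "1"))

    def to_bitstring(self) -> str:
        return "".join("1" if i in self.on_bits else "0" for i in range(self.length))


def cosine_distance(u: Sequence[float] | np.ndarray, v: Sequence[float] | np.ndarray) -> float:
    """1 - cos(u, v); exactly 0 for identical vectors; errors on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise AnalysisError("cosine distance undefined for a zero vector")
    if np.array_equal(u, v):
        return 0.0
    cos = float(np.dot(u, v) / (nu * nv))
    return float(min(max(1.0 - cos, 0.0), 2.0))


def tanimoto_distance(a: BitFingerprint, b: BitFingerprint) -> float:
    """1 - Jaccard coefficient of the two on-bit sets."""
    if a.length != b.length:
        raise ValidationError(f"fingerprint length mismatch: {a.length} vs {b.length}")
    union = a.on_bits | b.on_bits
    if not union:
        raise AnalysisError("Tanimoto distance undefined for two empty fingerprints")
    return 1.0 - len(a.on_bits & b.on_bits) / len(union)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal over labelled items."""

    labels: list[str]
    values: np.ndarray
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric within 1e-12")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.any(self.values < 0):
            raise ValidationError("distances must be nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def read_tsv(cls, path: str | Path, metric: str = "cosine") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        # squash read-back asymmetries below the symmetry tolerance
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls(list(df.index.astype(str)), values, metric=metric)


def pairwise_distances(
    items: Sequence, metric: str, labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Full symmetric distance matrix under ``tanimoto`` or ``cosine``.

    Items are bit fingerprints for ``tanimoto`` and numeric vectors for
    ``cosine``; element-level domain errors are re-raised naming both labels.
    """
    if metric not in ("tanimoto", "cosine"):
        raise ValidationError(f"unknown metric {metric!r}")
    n = len(items)
    if n < 2:
        raise ValidationError("pairwise distances need at least 2 items")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValidationError("labels length does not match items")
    dist = tanimoto_distance if metric == "tanimoto" else cosine_distance
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = dist(items[i], items[j])
            except AnalysisError as exc:
                raise AnalysisError(
                    f"{metric} distance undefined between "
                    f"{labels[i]!r} and {labels[j]!r}: {exc}"
                ) from exc
    return DistanceMatrix(list(labels), values, metric=metric)


@dataclass
class ClusterNode:
    """Node of a rooted binary merge tree; leaves carry a label."""

    height: float
    label: str | None = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:  # type: ignore[union-attr]
            out.extend(c.leaves())
        return out


@dataclass
class ClusterTree:
    root: ClusterNode
    linkage: str
    merge_heights: list[float] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def cut(self, k: int) -> list[frozenset[str]]:
        """Partition into k clusters by undoing the last k-1 merges."""
        n = len(self.root.leaves())
        if not (1 <= k <= n):
            raise ValidationError(f"cut k={k} outside [1, {n}]")
        clusters = [self.root]
        while len(clusters) < k:
            # split the internal node merged last (greatest height; ties by
            # smallest leaf label for determinism)
            internal = [c for c in clusters if not c.is_leaf]
            node = max(internal, key=lambda c: (c.height, sorted(c.leaves())[0]))
            clusters.remove(node)
            clusters.extend(node.children)  # type: ignore[arg-type]
        return [frozenset(c.leaves()) for c in clusters]

    def cut_labels(self, k: int) -> dict[str, int]:
        """Cluster assignment per label, clusters numbered by smallest member."""
        parts = sorted(self.cut(k), key=lambda s: sorted(s)[0])
        return {label: idx for idx, part in enumerate(parts) for label in part}

    def to_newick(self) -> str:
        """Newick export with branch lengths = merge-height differences."""

        def fmt(node: ClusterNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.label}:{length:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)  # type: ignore[union-attr]
            return f"({inner}):{length:.10g}"

        inner = ",".join(fmt(c, self.root.height) for c in self.root.children or ())
        return f"({inner});" if self.root.children else f"({self.root.label});"


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering with a deterministic tie-break.

    Among candidate pairs at the minimal current distance, the pair whose
    (sorted) leaf-label tuples compare lexicographically smallest is merged
    first. Cluster-cluster distances follow the Lance-Williams updates for
    single, complete and average (UPGMA) linkage.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; expected {LINKAGES}")
    n = len(dm.labels)
    if n < 2:
        raise AnalysisError("clustering requires at least 2 labels")

    nodes: dict[int, ClusterNode] = {
        i: ClusterNode(height=0.0, label=dm.labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: (dm.labels[i],) for i in range(n)}  # sorted leaf labels per cluster
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dm.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    next_id = n
    merge_heights: list[float] = []

    while len(active) > 1:
        best_pair = min(
            dist,
            key=lambda p: (dist[p], tuple(sorted((keys[p[0]], keys[p[1]])))),
        )
        a, b = best_pair
        h = dist[best_pair]
        merge_heights.append(h)
        # order children deterministically by smallest leaf label
        ca, cb = nodes[a], nodes[b]
        if keys[b] < keys[a]:
            ca, cb = cb, ca
        merged = ClusterNode(height=h, children=(ca, cb))
        mid = next_id
        next_id += 1
        nodes[mid] = merged
        sizes[mid] = sizes[a] + sizes[b]
        keys[mid] = tuple(sorted(keys[a] + keys[b]))
        active.discard(a)
        active.discard(b)
        new_dist = {}
        for c in active:
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            if linkage == "single":
                d = min(da, db)
            elif linkage == "complete":
                d = max(da, db)
            else:  # average (UPGMA)
                d = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            new_dist[(c, mid)] = d
        dist = {
            (i, j): v
            for (i, j), v in dist.items()
            if i in active and j in active
        }
        dist.update(new_dist)
        active.add(mid)

    root = nodes[next(iter(active))]
    return ClusterTree(root=root, linkage=linkage, merge_heights=merge_heights)


def target_vectors(matrix) -> tuple[list[str], np.ndarray]:
    """Per-drug binary target vectors d_i (rows of R)."""
    return list(matrix.drug_ids), matrix.to_dense()


def ligand_vectors(matrix) -> tuple[list[str], np.ndarray]:
    """Per-target binary ligand vectors t_j (columns of R)."""
    return list(matrix.target_ids), matrix.to_dense().T


def partition_agreement(
    partition_a: dict[str, int] | Iterable[frozenset[str]],
    partition_b: dict[str, int] | Iterable[frozenset[str]],
) -> float:
    """Adjusted Rand index between two partitions of the same label set."""

    def as_assignment(p) -> dict[str, int]:
        if isinstance(p, dict):
            return p
        return {label: idx for idx, part in enumerate(p) for label in part}

    a = as_assignment(partition_a)
    b = as_assignment(partition_b)
    if set(a) != set(b):
        raise ValidationError("partitions must cover the same label set")
    order = sorted(a)
    return float(adjusted_rand_score([a[x] for x in order], [b[x] for x in order]))
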