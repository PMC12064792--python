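"""Appearance-similarity grouping of species from a classifier confusion matrix.

A detector trained over all species confuses morphologically similar animals
(red deer vs fallow deer, rabbit vs hare) far more often than dissimilar ones.
This module turns that confusion structure into expert groups: the confusion
matrix is row-normalised into a similarity matrix, converted to a symmetric
dissimilarity, and clustered bottom-up (agglomerative, average linkage by
default).  Cutting the resulting dendrogram at K clusters yields the
assignment vector mapping each species to the expert model responsible
for it.

The linkage is implemented here rather than delegated so that tie-breaking is
fully specified (smallest index pair), which makes the merge sequence exactly
reproducible and checkable against a brute-force reference.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "SimilarityMatrix",
    "LinkageTree",
    "GroupAssignment",
    "similarity_from_confusion",
    "distance_from_similarity",
    "agglomerative_cluster",
    "group_species",
    "export_dendrogram",
    "plot_dendrogram",
]

_LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Species-by-species prediction counts.

    ``counts[i, j]`` is the number of instances of true species ``labels[i]``
    predicted as ``labels[j]``.
    """

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got shape {counts.shape}")
        if counts.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels but {counts.shape[0]} matrix rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate species labels")
        neg = np.argwhere(counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(f"negative count at row {i} ({self.labels[i]}), column {j}")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return len(self.labels)

    def drop(self, label: str) -> "ConfusionMatrix":
        """Return a copy without one label's row and column."""
        if label not in self.labels:
            raise KeyError(f"label {label!r} not in confusion matrix")
        keep = [i for i, lab in enumerate(self.labels) if lab != label]
        return ConfusionMatrix(
            tuple(self.labels[i] for i in keep), self.counts[np.ix_(keep, keep)]
        )

    def permuted(self, order: Sequence[int]) -> "ConfusionMatrix":
        order = list(order)
        return ConfusionMatrix(
            tuple(self.labels[i] for i in order), self.counts[np.ix_(order, order)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConfusionMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column species must match (same order)")
        return cls(tuple(str(c) for c in df.columns), df.to_numpy())

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConfusionMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Row-normalised confusion: ``values[i, j]`` is the fraction of species-i
    instances predicted as species j.  Rows whose source counts were all zero
    stay at zero and are listed in ``zero_rows``."""

    labels: tuple[str, ...]
    values: np.ndarray
    zero_rows: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "zero_rows", frozenset(self.zero_rows))

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class LinkageTree:
    """Merge history of an agglomeration over ``leaf_labels``.

    Nodes are numbered scipy-style: leaves ``0..N-1``, the node created by
    merge ``m`` is ``N + m``.  Each merge record is
    ``(node_a, node_b, height, merged_size)`` with ``node_a < node_b``.
    """

    leaf_labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")
        object.__setattr__(self, "leaf_labels", tuple(self.leaf_labels))
        object.__setattr__(self, "merges", tuple(tuple(m) for m in self.merges))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(m[2] for m in self.merges)

    def to_scipy(self) -> np.ndarray:
        """Linkage array compatible with :mod:`scipy.cluster.hierarchy`."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def cut(self, k: int) -> "GroupAssignment":
        """Cut the dendrogram into ``k`` clusters (apply the first N-k merges).

        Cluster ids are assigned 0..k-1 in order of each cluster's smallest
        leaf index, so the labelling is deterministic.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for m, (a, b, _h, _s) in enumerate(self.merges[: n - k]):
            members[n + m] = members.pop(a) + members.pop(b)
        clusters = sorted(members.values(), key=min)
        assignment = [0] * n
        for gid, leaves in enumerate(clusters):
            for leaf in leaves:
                assignment[leaf] = gid
        return GroupAssignment(self.leaf_labels, tuple(assignment), k)


@dataclass(frozen=True)
class GroupAssignment:
    """Per-species cluster id: species ``labels[i]`` belongs to expert group
    ``assignment[i]``, one of ``K`` groups."""

    labels: tuple[str, ...]
    assignment: tuple[int, ...]
    k: int
    group_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.assignment) != len(self.labels):
            raise ValueError("one cluster id per species required")
        present = set(self.assignment)
        if present != set(range(self.k)):
            raise ValueError(
                f"cluster ids must cover 0..{self.k - 1} with no gaps, got {sorted(present)}"
            )
        if self.group_names is not None and len(self.group_names) != self.k:
            raise ValueError("need one group name per cluster")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "assignment", tuple(int(a) for a in self.assignment))

    def group_of(self, label: str) -> int:
        try:
            return self.assignment[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"species {label!r} has no group assignment") from None

    def members(self, group_id: int) -> tuple[str, ...]:
        return tuple(
            lab for lab, g in zip(self.labels, self.assignment) if g == group_id
        )

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.labels, self.assignment))

    def groups(self) -> list[tuple[str, ...]]:
        return [self.members(g) for g in range(self.k)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "assignment": self.as_dict(),
            "group_names": list(self.group_names) if self.group_names else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupAssignment":
        payload = json.loads(Path(path).read_text())
        labels = tuple(payload["assignment"])
        assignment = tuple(payload["assignment"][lab] for lab in labels)
        names = payload.get("group_names")
        return cls(labels, assignment, int(payload["k"]),
                   tuple(names) if names else None)

    @classmethod
    def from_groups(cls, groups: Sequence[Sequence[str]],
                    group_names: Sequence[str] | None = None) -> "GroupAssignment":
        """Build an assignment directly from an explicit partition."""
        labels: list[str] = []
        assignment: list[int] = []
        for gid, members in enumerate(groups):
            for lab in members:
                labels.append(lab)
                assignment.append(gid)
        return cls(tuple(labels), tuple(assignment), len(groups),
                   tuple(group_names) if group_names else None)


def similarity_from_confusion(cm: ConfusionMatrix) -> SimilarityMatrix:
    """Row-normalise a confusion matrix into a similarity matrix.

    S_ij = C_ij / sum_k C_ik.  A species never observed (all-zero row) keeps a
    zero row and is recorded in ``zero_rows`` rather than producing NaNs.
    """
    counts = cm.counts.astype(float)
    row_sums = counts.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    safe = np.where(row_sums == 0, 1.0, row_sums)
    values = counts / safe[:, None]
    return SimilarityMatrix(cm.labels, values, frozenset(int(i) for i in zero))


def distance_from_similarity(sm: SimilarityMatrix) -> np.ndarray:
    """Symmetric dissimilarity from an (asymmetric) similarity matrix.

    D_ij = 1 - (S_ij + S_ji)/2 off the diagonal — one minus the mutual
    confusion rate — with D_ii = 0.  Entries lie in [0, 1].
    """
    s = sm.values
    d = 1.0 - (s + s.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def _validate_distances(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def agglomerative_cluster(
    distances: np.ndarray,
    k: int,
    labels: Sequence[str] | None = None,
    linkage: str = "average",
) -> tuple[LinkageTree, GroupAssignment]:
    """Agglomerate N items into a full merge tree and cut it at ``k`` clusters.

    Average linkage (UPGMA) by default; ``complete`` and ``single`` are
    available for sensitivity checks.  At every step the pair of active
    clusters at minimum linkage distance is merged; exact ties are broken by
    the smallest (i, j) node-index pair, which makes the merge sequence
    deterministic.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    d = _validate_distances(distances)
    n = d.shape[0]
    if labels is None:
        labels = tuple(f"item{i}" for i in range(n))
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError("label count must match matrix size")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    # Linkage distances are recomputed from the raw leaf matrix via fsum
    # (the exactly-rounded true sum), so they are independent of merge
    # history and traversal order: exact ties are well-defined, and the
    # smallest-(i, j) tie-break is exactly reproducible.
    def link(ma: list[int], mb: list[int]) -> float:
        cross = [float(d[i, j]) for i in ma for j in mb]
        if linkage == "average":
            return math.fsum(cross) / len(cross)
        return max(cross) if linkage == "complete" else min(cross)

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        (a, b) = min(dist, key=lambda p: (dist[p], p))
        h = dist[(a, b)]
        new = n + step
        merged = members.pop(a) + members.pop(b)
        merges.append((a, b, h, len(merged)))
        dist = {p: v for p, v in dist.items() if a not in p and b not in p}
        for c in members:
            dist[(c, new)] = link(members[c], merged)
        members[new] = merged

    tree = LinkageTree(labels, tuple(merges))
    return tree, tree.cut(k)


def group_species(
    cm: ConfusionMatrix,
    k: int,
    background_label: str | None = None,
    linkage: str = "average",
) -> GroupAssignment:
    """Cluster species into ``k`` expert groups from their confusion counts.

    The background row/column, if named, is removed first: expert groups
    contain species only.  Species never observed (all-zero confusion row)
    cannot be placed by the clustering itself; they are excluded from the
    agglomeration and attached afterwards to the group at minimum mean
    distance, with a warning.
    """
    if background_label is not None and background_label in cm.labels:
        cm = cm.drop(background_label)
    sm = similarity_from_confusion(cm)
    d = distance_from_similarity(sm)

    zero = sorted(sm.zero_rows)
    if not zero:
        _, assignment = agglomerative_cluster(d, k, labels=cm.labels, linkage=linkage)
        return assignment

    warnings.warn(
        f"species never observed (all-zero confusion rows): "
        f"{[cm.labels[i] for i in zero]}; assigned by nearest-group fallback",
        stacklevel=2,
    )
    keep = [i for i in range(cm.n) if i not in zero]
    if k > len(keep):
        raise ValueError(
            f"k={k} exceeds the {len(keep)} species with observations"
        )
    sub = d[np.ix_(keep, keep)]
    _, part = agglomerative_cluster(
        sub, k, labels=[cm.labels[i] for i in keep], linkage=linkage
    )
    assignment = {lab: g for lab, g in zip(part.labels, part.assignment)}
    for i in zero:
        means = [
            d[i, [keep[j] for j, g in enumerate(part.assignment) if g == gid]].mean()
            for gid in range(k)
        ]
        assignment[cm.labels[i]] = int(np.argmin(means))
    return GroupAssignment(
        cm.labels, tuple(assignment[lab] for lab in cm.labels), k
    )


def _newick_node(tree: LinkageTree, node: int, parent_h: float) -> str:
    n = tree.n_leaves
    if node < n:
        lab = tree.leaf_labels[node]
        if any(c in lab for c in "(),:; \t"):
            lab = f"'{lab}'"
        return f"{lab}:{parent_h / 2:.6g}"
    a, b, h, _ = tree.merges[node - n]
    inner = ",".join(_newick_node(tree, c, h) for c in (a, b))
    return f"({inner}):{(parent_h - h) / 2:.6g}"


def export_dendrogram(tree: LinkageTree, path: str | Path | None = None) -> str:
    """Serialise the merge tree as an ultrametric Newick string.

    Every leaf sits at depth (root merge height)/2, so the path length between
    two leaves equals the height at which they were merged.
    """
    n = tree.n_leaves
    if n == 1:
        newick = f"{tree.leaf_labels[0]};"
    else:
        a, b, h, _ = tree.merges[-1]
        parts = [_newick_node(tree, child, h) for child in (a, b)]
        newick = f"({','.join(parts)});"
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick


def plot_dendrogram(tree: LinkageTree, ax=None):
    """Draw the dendrogram (matplotlib axes returned)."""
    from scipy.cluster import hierarchy

    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(
        tree.to_scipy(), labels=list(tree.leaf_labels), ax=ax, leaf_rotation=90
    )
    ax.set_ylabel("mutual-confusion distance")
    return ax
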