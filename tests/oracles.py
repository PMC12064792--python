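"""Independent reference implementations used only as test oracles.

These deliberately re-derive results by brute force (naive re-averaging,
exhaustive enumeration) and share no code with the package internals they
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_linkage(d: np.ndarray, linkage: str = "average"):
    """Naive O(N^3) agglomeration: at every step, recompute every
    inter-cluster linkage distance directly from the raw leaf distance
    matrix, merge the minimum (ties to the smallest (i, j) node-id pair).

    Returns merge records (node_a, node_b, height, size) with scipy-style
    node numbering, matching the package's LinkageTree convention.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            cross = [float(d[i, j]) for i in clusters[a] for j in clusters[b]]
            if linkage == "average":
                dist = math.fsum(cross) / len(cross)
            elif linkage == "complete":
                dist = float(np.max(cross))
            else:
                dist = float(np.min(cross))
            key = (dist, a, b)
            if best is None or key < best:
                best = key
        dist, a, b = best
        new = n + step
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, dist, len(clusters[new])))
    return merges


def set_partitions(items, k):
    """All partitions of ``items`` into exactly k non-empty blocks."""
    items = list(items)
    if k == 1:
        yield [items]
        return
    if len(items) == k:
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    # first joins an existing block of a (k)-partition of rest
    for part in set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
    # first is its own block added to a (k-1)-partition of rest
    for part in set_partitions(rest, k - 1):
        yield [[first]] + part


def best_partition_by_within_distance(d: np.ndarray, k: int):
    """Exhaustive minimum of the mean within-cluster pairwise distance over
    every k-partition; returns the winning partition as a set of frozensets."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    best, best_score = None, np.inf
    for part in set_partitions(range(n), k):
        pairs = [
            d[i, j]
            for block in part
            for i, j in itertools.combinations(block, 2)
        ]
        score = float(np.mean(pairs)) if pairs else 0.0
        if score < best_score - 1e-12:
            best, best_score = part, score
    return {frozenset(block) for block in best}
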