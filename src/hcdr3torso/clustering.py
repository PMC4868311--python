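"""Greedy RMSD-threshold clustering of backbone fragments and loop decoys.

One algorithm serves two jobs: separating bulged from non-bulged torso
fragments at a 2 A radius, and grouping loop decoys (Calibur-style) with a
minimum-cluster-size filter. The algorithm is iterative center-based
clustering: the item with the most neighbours within the radius (ties broken
by lowest input index) becomes a representative; it and its neighbours form a
cluster and are removed; repeat until no items remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, superpose_rmsd


@dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple[str, ...]
    avg_rmsd_to_representative: float

    @property
    def size(self) -> int:
        return len(self.members)


def pairwise_rmsd(coords: list[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of superposition RMSDs between all coordinate sets."""
    n = len(coords)
    shapes = {np.asarray(c).shape for c in coords}
    if len(shapes) > 1:
        raise GeometryError(f"mixed coordinate-set shapes: {sorted(shapes)}")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = superpose_rmsd(coords[i], coords[j])
    return mat


def greedy_cluster(
    items: list[np.ndarray],
    radius: float,
    ids: list[str] | None = None,
) -> list[Cluster]:
    """Cluster coordinate sets by superposition RMSD at the given radius.

    Returns clusters in decreasing size (ties keep formation order). Every
    input item lands in exactly one cluster.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if not items:
        return []
    if ids is None:
        ids = [str(i) for i in range(len(items))]
    if len(ids) != len(items):
        raise ValueError("ids/items length mismatch")
    dist = pairwise_rmsd(items)
    remaining = list(range(len(items)))
    clusters = []
    while remaining:
        best_center, best_neighbors = None, None
        for i in remaining:
            neighbors = [j for j in remaining if dist[i, j] <= radius]
            if best_neighbors is None or len(neighbors) > len(best_neighbors):
                best_center, best_neighbors = i, neighbors
        members = tuple(ids[j] for j in best_neighbors)
        others = [j for j in best_neighbors if j != best_center]
        avg = float(np.mean([dist[best_center, j] for j in others])) if others else 0.0
        clusters.append(
            Cluster(
                representative=ids[best_center],
                members=members,
                avg_rmsd_to_representative=avg,
            )
        )
        removed = set(best_neighbors)
        remaining = [j for j in remaining if j not in removed]
    clusters.sort(key=lambda c: -c.size)  # stable: ties keep formation order
    return clusters


def cluster_decoys(
    models: list[tuple[str, np.ndarray]],
    threshold: float = 2.0,
    min_fraction: float = 0.01,
) -> list[Cluster]:
    """Cluster decoy loop coordinates and drop clusters below the size floor.

    Clusters with fewer than ceil(min_fraction * N) members are omitted
    (for 1000 models at the default 1% this keeps clusters of 10 or more);
    an empty list means no cluster survived.
    """
    if not (0 <= min_fraction < 1):
        raise ValueError(f"min_fraction must be in [0, 1), got {min_fraction}")
    ids = [m[0] for m in models]
    coords = [np.asarray(m[1], dtype=float) for m in models]
    clusters = greedy_cluster(coords, threshold, ids=ids)
    floor = math.ceil(min_fraction * len(models))
    return [c for c in clusters if c.size >= floor]
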