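"""Per-slice candidate-cluster construction (cluster generation).

A segmentation network occasionally hallucinates extra ventricle-like
regions (most often the right ventricle). The first stage of the clean-up
builds, for each slice, a small set of candidate clusters:

1. take the three largest connected components of the non-background mask;
2. if a component contains several separable IC+TZ cores, split it into one
   cluster per core and reassign each EL pixel to the nearest core
   (EL rings can enclose more than one cavity when the network bridges
   neighbouring structures);
3. merge any fragment smaller than 5% of the largest cluster into its
   nearest neighbour, treating it as an incorrectly enclosed mini-cluster.

Pixels and their class labels are conserved through steps 2-3; only
components beyond the third-largest are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import ClusterConfig
from .io import EL, IC, TZ, validate_label_map

__all__ = ["Cluster", "ClusterSet", "find_top_clusters", "split_cluster",
           "merge_small_clusters", "generate_clusters"]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


class Cluster:
    """A connected candidate-ventricle region within one slice.

    Holds the pixel coordinates (row, col), the class label of each pixel
    (EL=1, IC=2, TZ=3), and caches size, centroid, IC+TZ pixel count and a
    sorted flat-index array used for fast overlap computation.
    """

    __slots__ = ("coords", "labels", "shape", "size", "centroid", "ictz_size", "flat")

    def __init__(self, coords: np.ndarray, labels: np.ndarray, shape: Tuple[int, int]):
        coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
        labels = np.asarray(labels, dtype=np.uint8).reshape(-1)
        if coords.shape[0] == 0:
            raise ValueError("a cluster must contain at least one pixel")
        if coords.shape[0] != labels.shape[0]:
            raise ValueError("coords and labels length mismatch")
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        self.coords = coords[order]
        self.labels = labels[order]
        self.shape = (int(shape[0]), int(shape[1]))
        self.size = int(coords.shape[0])
        self.centroid = (float(self.coords[:, 0].mean()), float(self.coords[:, 1].mean()))
        self.ictz_size = int(np.count_nonzero((self.labels == IC) | (self.labels == TZ)))
        self.flat = self.coords[:, 0] * self.shape[1] + self.coords[:, 1]

    @property
    def pixel_set(self) -> Set[Tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}

    def label_counts(self) -> dict:
        counts = np.bincount(self.labels, minlength=4)
        return {EL: int(counts[EL]), IC: int(counts[IC]), TZ: int(counts[TZ])}

    def mask(self) -> np.ndarray:
        """Render the cluster back onto an empty slice."""
        out = np.zeros(self.shape, dtype=np.uint8)
        out[self.coords[:, 0], self.coords[:, 1]] = self.labels
        return out

    def is_connected(self, connectivity: int = 8) -> bool:
        m = np.zeros(self.shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        _, n = ndimage.label(m, structure=_structure(connectivity))
        return n == 1

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Cluster(size={self.size}, ictz={self.ictz_size}, "
                f"centroid=({self.centroid[0]:.1f},{self.centroid[1]:.1f}))")


def _sort_key(c: Cluster):
    # size descending; ties broken toward the smaller (row, col) centroid
    return (-c.size, c.centroid[0], c.centroid[1])


@dataclass
class ClusterSet:
    """Candidate clusters of one slice, size-descending, pairwise disjoint."""

    slice_index: int
    clusters: List[Cluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.clusters = sorted(self.clusters, key=_sort_key)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, i: int) -> Cluster:
        return self.clusters[i]


def find_top_clusters(label_map: np.ndarray, k: int = 3, connectivity: int = 8,
                      slice_index: int = 0) -> ClusterSet:
    """Largest ``k`` connected components of the non-background mask.

    Any set of EL/IC/TZ pixels connected under the given connectivity counts
    as one cluster; components beyond the k-th largest are discarded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = validate_label_map(label_map)
    lab, n = ndimage.label(arr > 0, structure=_structure(connectivity))
    clusters = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(lab == comp)
        clusters.append(Cluster(np.column_stack([rows, cols]), arr[rows, cols], arr.shape))
    clusters.sort(key=_sort_key)
    return ClusterSet(slice_index, clusters[:k])


def _squared_dists_to(points: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Exact integer squared Euclidean distance from each query to its
    nearest point of ``points``."""
    tree = cKDTree(points)
    d, _ = tree.query(queries)
    # distances between integer grid points: square and round back to int
    return np.rint(d * d).astype(np.int64)


def split_cluster(cluster: Cluster, connectivity: int = 8) -> List[Cluster]:
    """Split a cluster whose IC+TZ pixels fall in several components.

    Each IC+TZ component seeds one sub-cluster; every EL pixel joins the
    sub-cluster containing its nearest pixel (exact Euclidean nearest-pixel
    distance, ties toward the larger sub-cluster). Pixels and labels are
    conserved. A cluster with zero or one IC+TZ component is returned as-is.
    """
    ictz = (cluster.labels == IC) | (cluster.labels == TZ)
    if not ictz.any():
        return [cluster]
    m = np.zeros(cluster.shape, dtype=bool)
    ic_coords = cluster.coords[ictz]
    m[ic_coords[:, 0], ic_coords[:, 1]] = True
    lab, n = ndimage.label(m, structure=_structure(connectivity))
    if n <= 1:
        return [cluster]

    comp_of_ictz = lab[ic_coords[:, 0], ic_coords[:, 1]]  # 1..n
    comp_coords = [ic_coords[comp_of_ictz == c] for c in range(1, n + 1)]
    comp_labels = [cluster.labels[ictz][comp_of_ictz == c] for c in range(1, n + 1)]
    # order components: larger first, then smaller centroid (stable tie-break)
    order = sorted(range(n), key=lambda i: (-len(comp_coords[i]),
                                            tuple(comp_coords[i].mean(axis=0))))
    comp_coords = [comp_coords[i] for i in order]
    comp_labels = [comp_labels[i] for i in order]

    el_coords = cluster.coords[~ictz]
    el_labels = cluster.labels[~ictz]
    members = [[cc] for cc in comp_coords]
    member_labels = [[cl] for cl in comp_labels]
    if len(el_coords):
        d2 = np.column_stack([_squared_dists_to(cc, el_coords) for cc in comp_coords])
        # argmin returns the first (= larger component) among equal distances
        assign = np.argmin(d2, axis=1)
        for i in range(n):
            sel = assign == i
            if sel.any():
                members[i].append(el_coords[sel])
                member_labels[i].append(el_labels[sel])
    return [Cluster(np.concatenate(members[i]), np.concatenate(member_labels[i]), cluster.shape)
            for i in range(n)]


def _min_pair_dist2(a: Cluster, b: Cluster) -> int:
    d, _ = cKDTree(b.coords).query(a.coords)
    return int(np.rint((d * d).min()))


def merge_small_clusters(clusters: Sequence[Cluster], min_fraction: float = 0.05) -> List[Cluster]:
    """Merge fragments below ``min_fraction`` of the largest input cluster.

    The threshold is fixed from the largest cluster of the *input* list.
    Sub-threshold clusters are absorbed smallest-first into the cluster
    nearest by minimum pairwise pixel distance; the set is re-examined after
    every merge. Pixels and labels are conserved.
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must lie in (0, 1)")
    pool = sorted(clusters, key=_sort_key)
    if not pool:
        return []
    threshold = min_fraction * pool[0].size
    while len(pool) > 1:
        small = [c for c in pool if c.size < threshold]
        if not small:
            break
        victim = min(small, key=lambda c: (c.size, c.centroid[0], c.centroid[1]))
        rest = [c for c in pool if c is not victim]
        target = min(rest, key=lambda c: (_min_pair_dist2(victim, c),
                                          -c.size, c.centroid[0], c.centroid[1]))
        merged = Cluster(np.concatenate([target.coords, victim.coords]),
                         np.concatenate([target.labels, victim.labels]), target.shape)
        pool = sorted([c for c in rest if c is not target] + [merged], key=_sort_key)
    return pool


def generate_clusters(label_map: np.ndarray, config: Optional[ClusterConfig] = None,
                      slice_index: int = 0) -> ClusterSet:
    """Full per-slice pipeline: top-k components → IC+TZ split → 5% merge.

    The mini-cluster merge applies within each fragmented component only:
    fragments are artefacts of the split step ("the network may have
    incorrectly enclosed" a mini IC+TZ core inside one region), whereas
    separate components are genuine rival candidates that must stay
    distinct for the cross-slice selection to judge them.
    """
    cfg = config or ClusterConfig()
    top = find_top_clusters(label_map, k=cfg.top_k, connectivity=cfg.connectivity,
                            slice_index=slice_index)
    out: List[Cluster] = []
    for c in top:
        parts = split_cluster(c, connectivity=cfg.connectivity)
        if len(parts) > 1:
            parts = merge_small_clusters(parts, min_fraction=cfg.merge_fraction)
        out.extend(parts)
    return ClusterSet(slice_index, out)
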