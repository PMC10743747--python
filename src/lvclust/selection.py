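"""Cross-slice cluster selection: pick the one-ventricle track, skip the rest.

Given each slice's candidate clusters, the selection finds the sequence of
one cluster per slice most consistent with a single left ventricle moving
smoothly through the short-axis stack, and blanks slices where no candidate
can plausibly be the ventricle:

1. choose one cluster per (non-skipped) slice minimising the summed
   Euclidean distance between consecutive centroids (dynamic programming);
2. compute the overlap percentage of each adjacent pair along the track;
3. if every pair overlaps at least the threshold (20%), go to 6;
4. otherwise count, for each chosen cluster, how many other chosen clusters
   overlap it by more than the threshold ("valid overlaps");
5. add the earliest slice with the fewest valid overlaps to the skip list
   and return to 1;
6. on first arrival, mark surviving slices as fixed, clear the skip list and
   rerun (giving previously skipped slices a second chance constrained by
   the fixed track); on second arrival, stop;
7. emit the chosen cluster per slice; skipped slices come out blank.

Overlap percentage between clusters a, b (2D pixel sets, possibly from
different slices) is 100 * |a ∩ b| / min(|a|, |b|) — symmetric, and robust
to the ventricle tapering toward apex and base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np

from .clusters import Cluster, ClusterSet, generate_clusters
from .config import ClusterConfig, SelectionConfig
from .io import SegmentationStack, ValidationError

__all__ = ["SelectionResult", "overlap_percent", "min_distance_sequence",
           "select_ventricle", "apply_selection", "postprocess_stack"]


def overlap_percent(a: Cluster, b: Cluster) -> float:
    """100 * |a ∩ b| / min(|a|, |b|), on 2D pixel coordinates."""
    if a.shape != b.shape:
        raise ValidationError(f"clusters live on different grids: {a.shape} vs {b.shape}")
    inter = np.intersect1d(a.flat, b.flat, assume_unique=True).size
    return 100.0 * inter / min(a.size, b.size)


@dataclass
class SelectionResult:
    """Per-slice outcome: the chosen cluster, or None for skipped slices."""

    chosen: Dict[int, Optional[Cluster]]
    skipped: Set[int] = field(default_factory=set)
    passes: int = 1
    iterations: int = 1

    def cluster_for(self, slice_index: int) -> Optional[Cluster]:
        return self.chosen.get(slice_index)


def _centroid_dist(a: Cluster, b: Cluster) -> float:
    return float(np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1]))


def min_distance_sequence(
    candidates: Sequence[ClusterSet],
    skip_list: Optional[Set[int]] = None,
    fixed_choices: Optional[Mapping[int, int]] = None,
) -> Dict[int, Cluster]:
    """Minimum-total-centroid-distance choice of one cluster per slice.

    Skipped and candidate-less slices are removed from the chain, making
    their neighbours consecutive. ``fixed_choices`` pins a slice to the
    given candidate index. Exact dynamic programming; ties in total distance
    prefer larger total cluster size, then lexicographically smallest
    candidate indices.
    """
    skip = skip_list or set()
    fixed = dict(fixed_choices or {})
    chain = [cs.slice_index for cs in candidates
             if cs.slice_index not in skip and len(cs) > 0]
    sets = {cs.slice_index: cs for cs in candidates}
    if not chain:
        return {}

    def options(s: int) -> List[int]:
        return [fixed[s]] if s in fixed else list(range(len(sets[s])))

    # DP state per candidate: (total_dist, -total_size, index_tuple); tuple
    # comparison implements the tie-break exactly as exhaustive enumeration.
    first = chain[0]
    best = {j: (0.0, -sets[first][j].size, (j,)) for j in options(first)}
    for prev_s, s in zip(chain, chain[1:]):
        nxt = {}
        for j in options(s):
            cand = min(
                (key[0] + _centroid_dist(sets[prev_s][i], sets[s][j]),
                 key[1] - sets[s][j].size,
                 key[2] + (j,))
                for i, key in best.items()
            )
            nxt[j] = cand
        best = nxt
    _, _, indices = min(best.values())
    return {s: sets[s][j] for s, j in zip(chain, indices)}


def _valid_overlap_counts(chosen: Dict[int, Cluster], threshold: float) -> Dict[int, int]:
    slices = sorted(chosen)
    counts = {s: 0 for s in slices}
    for i, s in enumerate(slices):
        for t in slices[i + 1:]:
            if overlap_percent(chosen[s], chosen[t]) > threshold:
                counts[s] += 1
                counts[t] += 1
    return counts


def select_ventricle(
    candidates: Sequence[ClusterSet],
    config: Optional[SelectionConfig] = None,
) -> SelectionResult:
    """Run the two-pass skip-and-fix selection over one patient's slices."""
    cfg = config or SelectionConfig()
    thr = cfg.overlap_threshold_percent
    all_slices = [cs.slice_index for cs in candidates]
    empty = {cs.slice_index for cs in candidates if len(cs) == 0}

    skip_list: Set[int] = set()
    fixed: Dict[int, int] = {}
    sets = {cs.slice_index: cs for cs in candidates}
    reached_step6 = False
    passes = 1
    max_iter = 2 * max(1, len(all_slices)) + 2
    chosen: Dict[int, Cluster] = {}

    for iteration in range(1, max_iter + 1):
        chosen = min_distance_sequence(candidates, skip_list | empty, fixed)
        chain = sorted(chosen)
        adjacent_ok = all(
            overlap_percent(chosen[a], chosen[b]) >= thr
            for a, b in zip(chain, chain[1:])
        )
        if adjacent_ok:
            # step 6
            if reached_step6 or not chain:
                break
            fixed = {s: sets[s].clusters.index(chosen[s]) for s in chain}
            skip_list = set()
            reached_step6 = True
            passes = 2
            continue
        # steps 4-5
        counts = _valid_overlap_counts(chosen, thr)
        skippable = [s for s in chain if s not in fixed]
        if not skippable:
            break
        fewest = min(counts[s] for s in skippable)
        victim = min(s for s in skippable if counts[s] == fewest)
        skip_list.add(victim)
    else:  # pragma: no cover - termination bound is proven by construction
        raise RuntimeError("selection failed to terminate within the 2-pass bound")

    result_chosen: Dict[int, Optional[Cluster]] = {}
    skipped: Set[int] = set()
    for s in all_slices:
        if s in chosen:
            result_chosen[s] = chosen[s]
        else:
            result_chosen[s] = None
            skipped.add(s)
    return SelectionResult(result_chosen, skipped, passes=passes, iterations=iteration)


def apply_selection(stack: SegmentationStack, result: SelectionResult) -> SegmentationStack:
    """Blank everything outside the chosen cluster of each slice.

    Skipped slices become all-background; labels inside the chosen cluster
    are untouched.
    """
    out = np.zeros_like(stack.voxels)
    for i in range(stack.n_slices):
        cluster = result.cluster_for(i)
        if cluster is None:
            continue
        if cluster.shape != stack.slice_shape:
            raise ValidationError(
                f"cluster grid {cluster.shape} does not match stack slices {stack.slice_shape}")
        out[i, cluster.coords[:, 0], cluster.coords[:, 1]] = cluster.labels
    return stack.with_voxels(out)


def postprocess_stack(
    stack: SegmentationStack,
    cluster_config: Optional[ClusterConfig] = None,
    selection_config: Optional[SelectionConfig] = None,
) -> tuple[SegmentationStack, SelectionResult]:
    """Full hallucination-removal chain: generate → select → apply."""
    ccfg = cluster_config or ClusterConfig()
    candidates = [generate_clusters(stack[i], ccfg, slice_index=i)
                  for i in range(stack.n_slices)]
    result = select_ventricle(candidates, selection_config)
    return apply_selection(stack, result), result
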