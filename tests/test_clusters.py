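import numpy as np
import pytest
from hypothesis import given, strategies as st

from lvclust import (ClusterConfig, find_top_clusters, generate_clusters,
                     merge_small_clusters, split_cluster)
from lvclust.io import EL, IC, TZ

from conftest import make_cluster
from oracles import flood_fill_components, nearest_component_assignment


def disc(center, radius, shape):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def pixel_label_multiset(clusters):
    return sorted((int(r), int(c), int(l))
                  for cl in clusters for (r, c), l in zip(cl.coords, cl.labels))


# ---------------------------------------------------------------------------
# find_top_clusters
# ---------------------------------------------------------------------------

def test_all_background_yields_empty_set():
    assert len(find_top_clusters(np.zeros((16, 16), int))) == 0


def test_top_three_of_four_blobs():
    arr = np.zeros((60, 60), dtype=np.uint8)
    specs = [((10, 10), 100), ((10, 40), 50), ((40, 10), 30), ((40, 40), 10)]
    for (r, c), n in specs:
        rows = np.arange(n) // 10 + r
        cols = np.arange(n) % 10 + c
        arr[rows, cols] = EL
    top = find_top_clusters(arr, k=3)
    assert [c.size for c in top] == [100, 50, 30]


@pytest.mark.parametrize("connectivity", [4, 8])
def test_components_match_flood_fill_oracle(rng, connectivity):
    for _ in range(20):
        arr = (rng.random((32, 32)) < 0.35).astype(np.uint8) * rng.integers(1, 4, (32, 32))
        got = find_top_clusters(arr, k=10_000, connectivity=connectivity)
        expected = flood_fill_components(arr > 0, connectivity)
        assert sorted(len(c) for c in expected) == sorted(c.size for c in got)
        assert set(map(frozenset, expected)) == {frozenset(c.pixel_set) for c in got}


def test_single_blob_size_equals_foreground_count(rng):
    arr = np.zeros((32, 32), dtype=np.uint8)
    arr[disc((16, 16), 7, arr.shape)] = TZ
    [only] = find_top_clusters(arr, k=3).clusters
    assert only.size == int((arr > 0).sum())
    assert only.pixel_set == flood_fill_components(arr > 0)[0]


def test_clusters_disjoint_connected_and_size_sorted(rng):
    for _ in range(10):
        arr = (rng.random((32, 32)) < 0.3).astype(np.uint8) * 2
        top = find_top_clusters(arr, k=3)
        seen = set()
        sizes = [c.size for c in top]
        assert sizes == sorted(sizes, reverse=True)
        for c in top:
            assert c.is_connected(8)
            assert not (c.pixel_set & seen)
            seen |= c.pixel_set


# ---------------------------------------------------------------------------
# split_cluster
# ---------------------------------------------------------------------------

def ring_cluster():
    arr = np.zeros((32, 32), dtype=np.uint8)
    arr[disc((16, 16), 10, arr.shape)] = EL
    arr[disc((16, 16), 6, arr.shape)] = IC
    [c] = find_top_clusters(arr, k=1).clusters
    return c


def test_single_ictz_component_returned_unchanged():
    c = ring_cluster()
    assert split_cluster(c) == [c]


def two_cavity_cluster():
    arr = np.zeros((24, 50), dtype=np.uint8)
    arr[8:13, 5:46] = EL
    arr[disc((10, 10), 2, arr.shape)] = IC
    arr[disc((10, 40), 2, arr.shape)] = TZ
    [c] = find_top_clusters(arr, k=1).clusters
    return c


def test_two_cavities_split_with_nearest_el_assignment():
    c = two_cavity_cluster()
    parts = split_cluster(c)
    assert len(parts) == 2
    owner_of = {}
    for i, p in enumerate(parts):
        for pix in p.pixel_set:
            owner_of[pix] = i
    assert owner_of[(10, 20)] == owner_of[(10, 12)]   # joins the (10,10) cavity
    assert owner_of[(10, 35)] == owner_of[(10, 38)]   # joins the (10,40) cavity
    # conservation of the (pixel, label) multiset
    assert pixel_label_multiset(parts) == pixel_label_multiset([c])
    for p in parts:
        assert p.is_connected(8)


def test_split_matches_brute_force_nearest_pixel_oracle():
    c = two_cavity_cluster()
    parts = split_cluster(c)
    ictz_comps = [sorted(p.pixel_set & {tuple(map(int, xy))
                                        for xy, l in zip(c.coords, c.labels) if l != EL})
                  for p in parts]
    el_pixels = [tuple(map(int, xy)) for xy, l in zip(c.coords, c.labels) if l == EL]
    assign = nearest_component_assignment(el_pixels, [set(s) for s in ictz_comps])
    for pix, idx in zip(el_pixels, assign):
        assert pix in parts[idx].pixel_set


def test_split_conserves_pixels_on_random_clusters(rng):
    for _ in range(15):
        arr = np.zeros((24, 24), dtype=np.uint8)
        arr[(rng.random((24, 24)) < 0.4)] = EL
        for _ in range(3):
            r, c0 = rng.integers(2, 22, size=2)
            arr[disc((r, c0), 2, arr.shape)] = rng.integers(2, 4)
        for cl in find_top_clusters(arr, k=3):
            parts = split_cluster(cl)
            assert sum(p.size for p in parts) == cl.size
            assert pixel_label_multiset(parts) == pixel_label_multiset([cl])


# ---------------------------------------------------------------------------
# merge_small_clusters
# ---------------------------------------------------------------------------

def blob_cluster(origin, n, label=EL, shape=(80, 80)):
    rows = np.arange(n) // 10 + origin[0]
    cols = np.arange(n) % 10 + origin[1]
    return make_cluster(np.column_stack([rows, cols]),
                        np.full(n, label), shape)


def test_all_above_threshold_unchanged():
    a, b = blob_cluster((5, 5), 1000), blob_cluster((40, 40), 900)
    assert merge_small_clusters([a, b], 0.05) == [a, b]


def test_five_percent_fragment_absorbed():
    a, b = blob_cluster((5, 5), 1000), blob_cluster((40, 40), 30, label=TZ)
    merged = merge_small_clusters([a, b], 0.05)
    assert len(merged) == 1
    assert merged[0].size == 1030
    assert pixel_label_multiset(merged) == pixel_label_multiset([a, b])


def test_merge_chooses_nearest_cluster():
    big1 = blob_cluster((0, 0), 400)
    big2 = blob_cluster((60, 60), 400)
    tiny = blob_cluster((55, 55), 5, label=TZ)   # much closer to big2
    merged = merge_small_clusters([big1, big2, tiny], 0.05)
    sizes = sorted(c.size for c in merged)
    assert sizes == [400, 405]
    bigger = max(merged, key=lambda c: c.size)
    assert (55, 55) in bigger.pixel_set and (60, 60) in bigger.pixel_set


def test_merge_conserves_labels_on_random_inputs(rng):
    for _ in range(10):
        clusters = [blob_cluster(tuple(rng.integers(0, 60, 2)), int(n), label=int(rng.integers(1, 4)))
                    for n in rng.integers(1, 120, size=4)]
        # drop accidental overlaps: keep pairwise disjoint ones only
        kept, used = [], set()
        for c in clusters:
            if not (c.pixel_set & used):
                kept.append(c)
                used |= c.pixel_set
        merged = merge_small_clusters(kept, 0.05)
        assert pixel_label_multiset(merged) == pixel_label_multiset(kept)
        largest = max((c.size for c in kept), default=0)
        for c in merged:
            assert c.size >= 0.05 * largest or len(merged) == 1


def test_empty_input_gives_empty_output():
    assert merge_small_clusters([], 0.05) == []


# ---------------------------------------------------------------------------
# generate_clusters
# ---------------------------------------------------------------------------

def test_generate_on_blank_map_is_empty():
    assert len(generate_clusters(np.zeros((16, 16), int))) == 0


def test_true_ventricle_survives_beside_rv_mislabel(distractor_phantom):
    # a slice with the true LV plus an RV mimic must yield >= 2 clusters,
    # the true ventricle among them
    arr = distractor_phantom.stack[2]
    cs = generate_clusters(arr, slice_index=2)
    assert len(cs) >= 2
    truth = frozenset(distractor_phantom.ground_truth.chosen[2].pixel_set)
    assert any(frozenset(c.pixel_set) == truth for c in cs)


def test_generate_is_idempotent(rng, clean_phantom):
    for i in (0, 2):
        first = generate_clusters(clean_phantom.stack[i])
        canvas = np.zeros(clean_phantom.stack.slice_shape, dtype=np.uint8)
        for c in first:
            canvas[c.coords[:, 0], c.coords[:, 1]] = c.labels
        second = generate_clusters(canvas)
        assert pixel_label_multiset(first.clusters) == pixel_label_multiset(second.clusters)
        assert [c.size for c in first] == [c.size for c in second]


def test_generate_deterministic(rng):
    arr = (rng.random((48, 48)) < 0.3).astype(np.uint8) * rng.integers(1, 4, (48, 48))
    a = generate_clusters(arr)
    b = generate_clusters(arr)
    assert pixel_label_multiset(a.clusters) == pixel_label_multiset(b.clusters)
    assert [c.centroid for c in a] == [c.centroid for c in b]


@given(st.integers(0, 2**31 - 1))
def test_generate_output_disjoint_and_conserving(seed):
    rng = np.random.default_rng(seed)
    arr = (rng.random((20, 20)) < 0.35).astype(np.uint8) * rng.integers(1, 4, (20, 20))
    cfg = ClusterConfig()
    out = generate_clusters(arr, cfg)
    seen = set()
    for c in out:
        assert not (c.pixel_set & seen)
        seen |= c.pixel_set
    # retained components' pixels keep their labels
    for c in out:
        for (r, co), l in zip(c.coords, c.labels):
            assert arr[r, co] == l
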