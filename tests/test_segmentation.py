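"""Clustering-threshold segmentation, component cleanup and live wire."""

import heapq

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctffr.errors import ValidationError
from ctffr.phantom import PhantomSpec, lumen_mask, make_vessel_geometry, rasterize_ct
from ctffr.segmentation import (
    apply_threshold,
    class_stats,
    largest_component,
    live_wire,
    objective_G,
    optimal_threshold,
)


def brute_force_argmin(volume, t_min, t_max, step=1.0):
    """Independent exhaustive scan: evaluate G at every t, first minimum wins."""
    ts = np.arange(t_min, t_max + 0.5 * step, step)
    gs = [objective_G(volume, t) for t in ts]
    return float(ts[int(np.argmin(gs))])


class TestClassStats:
    def test_constant_volume_one_class(self):
        vol = np.full((3, 3, 3), 42.0)
        a1, a2, m1, m2, abar = class_stats(vol, t=40.0)
        assert (a1, m1, m2) == (42.0, 27, 0)
        assert np.isnan(a2)
        assert abar == 42.0

    def test_two_valued_forced_arithmetic(self):
        vol = np.array([[[0.0] * 3 + [100.0] * 5]])
        a1, a2, m1, m2, abar = class_stats(vol, t=50.0)
        assert (a1, a2, m1, m2) == (100.0, 0.0, 5, 3)
        assert abar == pytest.approx(100 * 5 / 8)

    def test_means_match_direct_summation(self, rng):
        vol = rng.uniform(0, 255, size=(4, 4, 1))
        t = 120.0
        a1, a2, m1, m2, abar = class_stats(vol, t)
        fg = vol[vol >= t]
        bg = vol[vol < t]
        assert a1 == pytest.approx(fg.sum() / fg.size)
        assert a2 == pytest.approx(bg.sum() / bg.size)
        assert (m1, m2) == (fg.size, bg.size)
        # abar is the count-weighted combination of the class means
        assert abar == pytest.approx((m1 * a1 + m2 * a2) / (m1 + m2))


class TestObjective:
    def test_pure_classes_have_zero_scatter(self):
        vol = np.array([[[0.0, 0.0, 100.0, 100.0]]])
        assert objective_G(vol, 50.0) == 0.0

    def test_constant_volume_zero_everywhere(self):
        vol = np.full((2, 2, 2), 7.0)
        for t in (0.0, 7.0, 10.0):
            assert objective_G(vol, t) == 0.0

    def test_matches_two_pass_brute_force(self, rng):
        vol = rng.integers(0, 256, size=(8, 8, 1)).astype(float)
        for t in range(0, 257, 8):
            fg = vol[vol >= t]
            bg = vol[vol < t]
            expected = 0.0
            for cls in (fg, bg):
                if cls.size:
                    expected += np.sum((cls - cls.mean()) ** 2)
            assert objective_G(vol, float(t)) == pytest.approx(expected, rel=1e-12)


class TestOptimalThreshold:
    def test_bimodal_tie_breaks_to_smallest_t(self):
        vol = np.array([[[0.0] * 4 + [100.0] * 4]])
        res = optimal_threshold(vol)
        assert res.objective.min() == 0.0
        assert res.threshold == 1.0  # smallest scanned t above the low mode

    def test_gaussian_mixture_matches_exhaustive_scan(self, rng):
        vol = np.concatenate([
            rng.normal(30, 10, size=500), rng.normal(120, 10, size=500)
        ]).reshape(10, 10, 10)
        res = optimal_threshold(vol)
        expected = brute_force_argmin(vol, res.thresholds[0], res.thresholds[-1])
        assert res.threshold == expected

    def test_result_invariants(self, rng):
        vol = rng.integers(0, 100, size=(6, 6, 6)).astype(float)
        res = optimal_threshold(vol)
        assert res.foreground_count + res.background_count == vol.size
        weighted = (res.foreground_count * res.foreground_mean
                    + res.background_count * res.background_mean) / vol.size
        assert res.overall_mean == pytest.approx(weighted)
        assert res.objective.min() == res.objective[
            np.flatnonzero(res.thresholds == res.threshold)[0]]

    def test_phantom_segmentation_recovers_lumen(self):
        spec = PhantomSpec(
            geometry=make_vessel_geometry(severity=0.5),
            spacing=(0.5, 0.5, 0.5), noise_sd=5.0, seed=21,
        )
        vol = rasterize_ct(spec)
        res = optimal_threshold(vol)
        mask = largest_component(apply_threshold(vol, res.threshold))
        truth = lumen_mask(spec)
        jaccard = (mask.data & truth).sum() / (mask.data | truth).sum()
        assert jaccard > 0.9

    def test_empty_scan_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            optimal_threshold(rng.random((3, 3, 3)), t_min=10, t_max=5)

    def test_kmeans_fixed_point_on_separated_modes(self, rng):
        vol = np.concatenate([
            rng.normal(20, 5, size=400), rng.normal(180, 5, size=400)
        ]).reshape(8, 10, 10)
        res = optimal_threshold(vol)
        v = vol.reshape(-1)
        fg = v >= res.threshold
        # at t*, every voxel is nearer its own class mean (2-means fixed point)
        assert (np.abs(v[fg] - res.foreground_mean)
                <= np.abs(v[fg] - res.background_mean)).all()
        assert (np.abs(v[~fg] - res.background_mean)
                <= np.abs(v[~fg] - res.foreground_mean)).all()


class TestApplyThreshold:
    def test_extreme_thresholds(self, rng):
        vol = rng.uniform(10, 20, (3, 3, 3))
        assert apply_threshold(vol, 5.0).all()
        assert not apply_threshold(vol, 25.0).any()

    def test_elementwise_oracle(self, rng):
        vol = rng.uniform(0, 1, (4, 4, 4))
        assert np.array_equal(apply_threshold(vol, 0.5), vol >= 0.5)

    @settings(max_examples=30, deadline=None)
    @given(t1=st.floats(0, 1), t2=st.floats(0, 1), seed=st.integers(0, 1000))
    def test_foreground_antimonotone_in_threshold(self, t1, t2, seed):
        vol = np.random.default_rng(seed).random((4, 4, 4))
        lo, hi = min(t1, t2), max(t1, t2)
        assert not (apply_threshold(vol, hi) & ~apply_threshold(vol, lo)).any()


def flood_fill_components(mask, connectivity=26):
    """Independent BFS flood fill for component counting."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                manh = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and manh > 1:
                    continue
                if connectivity == 18 and manh > 2:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        comp = []
        stack = [idx]
        seen[idx] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(p[i] + off[i] for i in range(3))
                if all(0 <= q[i] < mask.shape[i] for i in range(3)) \
                        and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


class TestLargestComponent:
    def test_isolated_voxel_removed(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 3:5, 3:5] = True
        mask[7, 7, 7] = True
        out = largest_component(mask)
        assert not out[7, 7, 7]
        assert out.sum() == mask.sum() - 1

    def test_equal_components_tie_break_by_linear_index(self):
        mask = np.zeros((3, 9, 1), dtype=bool)
        mask[:, 6:8, 0] = True   # appears earlier in linear order? no: y=6..7
        mask[:, 0:2, 0] = True   # y=0..1 -> lower linear index
        out = largest_component(mask, connectivity=6)
        assert out[:, 0:2, 0].all() and not out[:, 6:8, 0].any()

    def test_matches_flood_fill_oracle(self, rng):
        mask = rng.random((10, 10, 10)) > 0.7
        for conn in (6, 18, 26):
            comps = flood_fill_components(mask, conn)
            if not comps:
                continue
            biggest = max(len(c) for c in comps)
            out = largest_component(mask, connectivity=conn)
            assert out.sum() == biggest
            assert flood_fill_components(out, conn).__len__() == 1

    def test_empty_mask_warns_and_passes_through(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning):
            out = largest_component(mask)
        assert not out.any()

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValidationError):
            largest_component(np.ones((2, 2, 2), dtype=bool), connectivity=4)


def dijkstra_oracle(cost, seed, target):
    """Independent heap Dijkstra on the same step rule."""
    dist = {seed: 0.0}
    heap = [(0.0, seed)]
    done = set()
    while heap:
        d, p = heapq.heappop(heap)
        if p in done:
            continue
        done.add(p)
        if p == target:
            return d
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                q = (p[0] + di, p[1] + dj)
                if not (0 <= q[0] < cost.shape[0] and 0 <= q[1] < cost.shape[1]):
                    continue
                w = cost[q] * (np.sqrt(2.0) if di and dj else 1.0)
                nd = d + w
                if nd < dist.get(q, np.inf):
                    dist[q] = nd
                    heapq.heappush(heap, (nd, q))
    raise AssertionError("unreachable target")


class TestLiveWire:
    def test_seed_equals_target(self, rng):
        img = rng.random((10, 10))
        path = live_wire(img, (3, 3), (3, 3))
        assert path.points == [(3, 3)] and path.cost == 0.0

    def test_flat_image_gives_geometric_shortest_path(self):
        img = np.full((15, 15), 5.0)
        path = live_wire(img, (2, 2), (10, 14))
        # flat cost c0 = w_g (gradient term only; Laplacian is identically 0)
        di, dj = 8, 12
        geometric = (min(di, dj) * np.sqrt(2.0) + abs(di - dj))
        assert path.cost == pytest.approx(0.8 * geometric, rel=1e-9)

    def test_path_is_8_connected_from_seed_to_target(self, rng):
        img = rng.random((12, 12))
        path = live_wire(img, (0, 0), (11, 11))
        assert path.points[0] == (0, 0) and path.points[-1] == (11, 11)
        for a, b in zip(path.points, path.points[1:]):
            assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    def test_cost_matches_independent_dijkstra(self, rng):
        from ctffr.segmentation import _local_cost

        img = rng.random((12, 12)) * 100
        cost = _local_cost(img, 0.8, 0.2)
        path = live_wire(img, (1, 2), (10, 9))
        assert path.cost == pytest.approx(dijkstra_oracle(cost, (1, 2), (10, 9)), rel=1e-12)

    def test_points_outside_slice_rejected(self, rng):
        img = rng.random((5, 5))
        with pytest.raises(ValidationError):
            live_wire(img, (0, 0), (5, 5))
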