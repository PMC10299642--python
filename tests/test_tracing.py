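"""Filament tracer: optimality, length metrics, per-larva aggregation."""

import heapq
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinoquant.synthetic import VoxelGrid, simulate_length_study
from kinoquant.tracing import (
    NoPathError,
    TracedPath,
    euclidean_length,
    is_measurable,
    measure,
    path_length,
    per_larva_top5,
    trace,
)

from conftest import make_filament_scene

SXY, SZ = 0.064, 0.65


def dijkstra_min_cost(data, base, tip, sxy, sz):
    """Independent shortest-path oracle on the 26-connected voxel graph.

    Edge cost = physical step length times the mean of (I_max - I + 1) at
    the two endpoints; plain binary-heap Dijkstra.
    """
    cost = data.max() - data.astype(float) + 1.0
    shape = data.shape
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3)
               if o != (0, 0, 0)]
    steps = [np.sqrt((o[0] * sz) ** 2 + (o[1] * sxy) ** 2 + (o[2] * sxy) ** 2)
             for o in offsets]
    dist = {base: 0.0}
    heap = [(0.0, base)]
    while heap:
        d, u = heapq.heappop(heap)
        if u == tip:
            return d
        if d > dist.get(u, np.inf):
            continue
        for o, s in zip(offsets, steps):
            v = (u[0] + o[0], u[1] + o[1], u[2] + o[2])
            if not all(0 <= vi < ni for vi, ni in zip(v, shape)):
                continue
            nd = d + s * (cost[u] + cost[v]) / 2.0
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return np.inf


def path_cost(data, voxels, sxy, sz):
    cost = data.max() - data.astype(float) + 1.0
    total = 0.0
    for u, v in zip(voxels[:-1], voxels[1:]):
        step = np.sqrt(((u[0] - v[0]) * sz) ** 2 + ((u[1] - v[1]) * sxy) ** 2
                       + ((u[2] - v[2]) * sxy) ** 2)
        total += step * (cost[tuple(u)] + cost[tuple(v)]) / 2.0
    return total


class TestTrace:
    def test_bright_straight_ridge_is_followed(self):
        data = np.full((3, 9, 40), 10, dtype=np.uint16)
        data[1, 4, :] = 4000
        grid = VoxelGrid(data, SXY, SZ)
        path = trace(grid, (1, 4, 0), (1, 4, 39))
        assert np.all(np.abs(path.voxels[:, 1] - 4) <= 1)
        assert np.all(np.abs(path.voxels[:, 0] - 1) <= 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_cost_matches_bruteforce_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 1000, size=(5, 5, 5)).astype(np.uint16)
        grid = VoxelGrid(data, SXY, SZ)
        base = tuple(rng.integers(0, 5, size=3))
        tip = tuple(rng.integers(0, 5, size=3))
        if base == tip:
            tip = (4 - tip[0], tip[1], tip[2])
        path = trace(grid, base, tip)
        assert path.base == base and path.tip == tip
        expected = dijkstra_min_cost(data, base, tip, SXY, SZ)
        assert path_cost(data, path.voxels, SXY, SZ) == pytest.approx(
            expected, abs=1e-9)

    def test_identical_seeds_single_point_zero_length(self, flat_grid):
        with pytest.warns(UserWarning, match="coincide"):
            path = trace(flat_grid, (1, 2, 3), (1, 2, 3))
        assert len(path) == 1
        result = measure(path)
        assert result.euclidean_um == 0.0 and result.path_um == 0.0

    def test_masked_wall_raises_no_path(self, flat_grid):
        mask = np.ones(flat_grid.shape, dtype=bool)
        mask[:, :, 8] = False
        with pytest.raises(NoPathError):
            trace(flat_grid, (1, 2, 2), (1, 2, 14), mask=mask)

    def test_seed_outside_grid_raises(self, flat_grid):
        with pytest.raises(ValueError, match="seed"):
            trace(flat_grid, (0, 0, 0), (0, 0, 99))


class TestLengthMetrics:
    def test_single_axis_pythagoras(self):
        path = TracedPath(np.array([[i, 0, 0] for i in range(11)]), SXY, SZ)
        assert euclidean_length(path) == pytest.approx(6.5, abs=1e-12)

    def test_3_4_5_triangle(self):
        path = TracedPath(np.array([[0, 0, 0], [0, 1, 1], [0, 2, 2],
                                    [0, 3, 3], [0, 3, 4]]), 1.0, 1.0)
        assert euclidean_length(path) == pytest.approx(5.0, abs=1e-12)

    def test_formula_oracle_on_random_endpoints(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.integers(0, 50, size=(2, 3))
            if np.all(a == b) or np.abs(a - b).max() > 1:
                # build a 2-point path only when endpoints are neighbors;
                # otherwise check the formula through physical points
                dz, dy, dx = (b - a).astype(float)
                expected = np.sqrt((dx * SXY) ** 2 + (dy * SXY) ** 2
                                   + (dz * SZ) ** 2)
                path = TracedPath(np.array([a]), SXY, SZ)
                path.voxels = np.array([a, b])  # bypass neighbor invariant
                assert euclidean_length(path) == pytest.approx(expected,
                                                               abs=1e-9)

    def test_collinear_path_arc_equals_chord(self):
        path = TracedPath(np.array([[0, i, i] for i in range(9)]), 1.0, 1.0)
        assert path_length(path) == pytest.approx(euclidean_length(path),
                                                  abs=1e-12)

    def test_right_angle_legs(self):
        voxels = [[0, i, 0] for i in range(4)] + [[0, 3, j] for j in range(1, 5)]
        path = TracedPath(np.array(voxels), 1.0, 1.0)
        assert path_length(path) == pytest.approx(7.0, abs=1e-12)
        assert euclidean_length(path) == pytest.approx(5.0, abs=1e-12)

    def test_traced_curved_filament_recovers_arc_length(self, curved_scene):
        grid, manifest = curved_scene
        base, tip = manifest.tracer_seeds(grid.spacing_xy, grid.spacing_z)[0]
        result = measure(trace(grid, base, tip), method="arc")
        assert result.path_um == pytest.approx(32.0, rel=0.05)

    def test_noise_free_straight_recovery_within_voxel_diagonal(self,
                                                                straight_scene):
        grid, manifest = straight_scene
        base, tip = manifest.tracer_seeds(grid.spacing_xy, grid.spacing_z)[0]
        chord = euclidean_length(trace(grid, base, tip))
        diagonal = np.sqrt(2 * grid.spacing_xy ** 2 + grid.spacing_z ** 2)
        assert abs(chord - manifest.curves[0].chord_length) <= diagonal

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(list(itertools.product((-1, 0, 1),
                                                           repeat=3))[:13]),
                    min_size=1, max_size=30))
    def test_chord_never_exceeds_arc(self, steps):
        # cumulative sums of half-space steps cannot revisit a voxel
        steps = [s for s in steps if s != (0, 0, 0)]
        if not steps:
            steps = [(-1, 0, 0)]
        voxels = np.cumsum([[10, 40, 40]] + steps, axis=0)
        path = TracedPath(voxels, SXY, SZ)
        assert euclidean_length(path) <= path_length(path) + 1e-12
        assert euclidean_length(path) <= path_length(path, smooth_um=2.0) + 1e-9

    def test_noise_never_improves_length_error(self):
        # mean absolute arc-length error over a fixed scene set must be
        # non-decreasing in additive noise (three levels, fixed seeds)
        def mean_error(noise_sd):
            errs = []
            for amp, seed in [(1.0, 3), (1.5, 4), (2.0, 5), (2.5, 6),
                              (3.0, 7), (3.5, 8)]:
                grid, manifest = make_filament_scene(
                    length_um=32.0, curvature_amp=amp, noise_sd=noise_sd,
                    seed=seed)
                base, tip = manifest.tracer_seeds(grid.spacing_xy,
                                                  grid.spacing_z)[0]
                arc = measure(trace(grid, base, tip)).path_um
                errs.append(abs(arc - 32.0))
            return np.mean(errs)

        errors = [mean_error(sd) for sd in (0.0, 150.0, 600.0)]
        assert errors[0] <= errors[1] <= errors[2]


class TestMeasurable:
    def test_bright_path_is_measurable_dim_is_not(self, straight_scene):
        grid, manifest = straight_scene
        base, tip = manifest.tracer_seeds(grid.spacing_xy, grid.spacing_z)[0]
        path = trace(grid, base, tip)
        assert is_measurable(grid, path, background=100.0, noise_sd=50.0)
        # a path through pure background fails the criterion
        corner = TracedPath(np.array([[0, 0, 0], [0, 0, 1]]),
                            grid.spacing_xy, grid.spacing_z)
        assert not is_measurable(grid, corner, background=100.0, noise_sd=50.0)


class TestPerLarvaTop5:
    def test_mean_of_exactly_five(self):
        df = pd.DataFrame({
            "group": "g", "larva": "L1",
            "kinocilium": [f"k{i}" for i in range(5)],
            "length_um": [30.0, 31.0, 32.0, 33.0, 34.0],
            "measurable": True,
        })
        out = per_larva_top5(df)
        assert len(out) == 1
        assert out["mean_um"].iloc[0] == pytest.approx(32.0)

    def test_top5_selection_ignores_short_kinocilia(self):
        lengths = [20.0, 25.0, 30.0, 31.0, 32.0, 33.0, 34.0]
        df = pd.DataFrame({
            "group": "g", "larva": "L1",
            "kinocilium": [f"k{i}" for i in range(7)],
            "length_um": lengths, "measurable": True,
        })
        assert per_larva_top5(df)["mean_um"].iloc[0] == pytest.approx(32.0)

    def test_matches_sort_oracle_on_random_larvae(self):
        rng = np.random.default_rng(7)
        rows = []
        for li in range(50):
            for ki in range(int(rng.integers(5, 12))):
                rows.append(("g", f"L{li:02d}", f"k{ki}",
                             float(rng.uniform(10, 40)), True))
        df = pd.DataFrame(rows, columns=["group", "larva", "kinocilium",
                                         "length_um", "measurable"])
        out = per_larva_top5(df).set_index("larva")["mean_um"]
        for larva, sub in df.groupby("larva"):
            expected = np.mean(sorted(sub["length_um"])[-5:])
            assert out[larva] == pytest.approx(expected, abs=1e-12)

    def test_larva_with_few_measurable_is_dropped_with_warning(self, caplog):
        df = pd.DataFrame({
            "group": "g", "larva": ["L1"] * 5 + ["L2"] * 5,
            "kinocilium": [f"k{i}" for i in range(10)],
            "length_um": 30.0,
            "measurable": [True] * 5 + [True, True, False, False, False],
        })
        with caplog.at_level("WARNING"):
            out = per_larva_top5(df)
        assert list(out["larva"]) == ["L1"]
        assert "L2" in caplog.text

    def test_larva_in_two_groups_rejected(self):
        df = pd.DataFrame({
            "group": ["a"] * 5 + ["b"] * 5, "larva": "L1",
            "kinocilium": [f"k{i}" for i in range(10)],
            "length_um": 30.0, "measurable": True,
        })
        with pytest.raises(ValueError, match="multiple groups"):
            per_larva_top5(df)

    def test_simulated_study_feeds_aggregation(self):
        spec = {"a": dict(true_mean=35.0, sd_between_larvae=1.0,
                          sd_within_larva=2.0, n_larvae=4,
                          kinocilia_per_larva=8)}
        out = per_larva_top5(simulate_length_study(spec, rng_seed=0))
        assert len(out) == 4
        # top-5 mean of 8 draws sits above the raw mean
        assert out["mean_um"].mean() > 35.0
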