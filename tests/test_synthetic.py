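"""Generator contracts: geometry, determinism, coverage, coupling,
event statistics, remapping modes, object sessions."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from placetopo import synthetic as syn
from placetopo.core import ParameterError


class TestTrajectory:
    def test_short_trajectory_stays_inside_arena(self, arena):
        traj = syn.simulate_trajectory(arena, 0.1, seed=0)
        assert traj.n_samples >= 1
        assert np.all((traj.x >= 0) & (traj.x <= arena.side_length))
        assert np.all((traj.y >= 0) & (traj.y <= arena.side_length))

    def test_same_seed_gives_identical_path(self, arena):
        a = syn.simulate_trajectory(arena, 10.0, seed=42)
        b = syn.simulate_trajectory(arena, 10.0, seed=42)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_35min_session_covers_arena(self, arena):
        traj = syn.simulate_trajectory(arena, 2100.0, seed=3)
        ij = np.floor(np.column_stack([traj.x, traj.y]) / 2.5).astype(int)
        ij = np.clip(ij, 0, 31)
        visited = np.zeros((32, 32), bool)
        visited[ij[:, 0], ij[:, 1]] = True
        assert visited.mean() >= 0.95

    def test_mean_speed_is_honored(self, arena):
        traj = syn.simulate_trajectory(arena, 600.0, mean_speed=10.0, seed=4)
        v = traj.speed(smooth_sigma_s=0.0)
        assert 8.0 < np.mean(v) < 12.0

    @pytest.mark.parametrize("bad", [dict(duration=0.0), dict(duration=10.0, mean_speed=-1)])
    def test_invalid_parameters_rejected(self, arena, bad):
        with pytest.raises(ParameterError):
            syn.simulate_trajectory(arena, **bad, seed=0)


class TestPopulation:
    def test_minimum_soma_spacing(self, population_60):
        anat = np.array([c.anatomical_centroid for c in population_60])
        assert pdist(anat).min() >= 10.0

    def test_overpacked_fov_raises(self, arena):
        with pytest.raises(ParameterError):
            syn.place_field_population(
                200, arena, syn.FovSpec(40.0, 40.0), seed=0
            )

    def test_zero_coupling_decouples_anatomy_and_fields(self, arena, fov):
        """Across 20 independent populations the anatomical/field distance
        correlation is centred on zero."""
        rs = []
        for i in range(20):
            cells = syn.place_field_population(
                300, arena, fov, active_fraction=1.0, seed=500 + i
            )
            anat = np.array([c.anatomical_centroid for c in cells])
            fx = np.array([c.field_centroids[0] for c in cells])
            rs.append(np.corrcoef(pdist(anat), pdist(fx))[0, 1])
        assert abs(np.mean(rs)) < 0.02
        assert np.max(np.abs(rs)) < 0.1

    def test_strong_coupling_correlates_distances_within_scale(self, arena, fov):
        scale = 350.0
        rs = []
        for i in range(3):
            cells = syn.place_field_population(
                300, arena, fov, active_fraction=1.0,
                clustering=syn.ClusteringConfig(0.9, scale), seed=600 + i,
            )
            anat = np.array([c.anatomical_centroid for c in cells])
            fx = np.array([c.field_centroids[0] for c in cells])
            ad, fd = pdist(anat), pdist(fx)
            m = ad <= scale
            rs.append(np.corrcoef(ad[m], fd[m])[0, 1])
        assert np.mean(rs) > 0.5

    def test_active_fraction(self, arena, fov):
        cells = syn.place_field_population(
            1000, arena, syn.FovSpec(1000.0, 1000.0), active_fraction=0.35, seed=7
        )
        frac = np.mean([c.active for c in cells])
        assert 0.30 < frac < 0.40

    def test_positions_within_bounds(self, population_60, arena, fov):
        for c in population_60:
            assert 0 <= c.anatomical_centroid[0] <= fov.width
            assert 0 <= c.anatomical_centroid[1] <= fov.height
            for fxy in c.field_centroids:
                assert 0 <= fxy[0] <= arena.side_length
                assert 0 <= fxy[1] <= arena.side_length


class TestEvents:
    def test_zero_intensity_gives_empty_train(self, traj_20min):
        cell = syn.SyntheticCellSpec(
            cell_id=0, anatomical_centroid=(10, 10),
            field_centroids=[(40.0, 40.0)], peak_event_rate=0.0,
        )
        rec = syn.generate_events(cell, traj_20min, noise_rate=0.0, seed=0)
        assert rec.n_events == 0

    def test_field_recovered_by_direct_histogram(self, arena, traj_20min):
        cell = syn.SyntheticCellSpec(
            cell_id=0, anatomical_centroid=(10, 10),
            field_centroids=[(40.0, 40.0)], peak_event_rate=3.0,
        )
        rec = syn.generate_events(cell, traj_20min, noise_rate=0.0, seed=1)
        # direct histogramming, no pipeline smoothing
        frames = np.searchsorted(traj_20min.t, rec.events_t) - 1
        occ, xe, ye = np.histogram2d(
            traj_20min.x, traj_20min.y, bins=16, range=[[0, 80], [0, 80]]
        )
        ev, _, _ = np.histogram2d(
            traj_20min.x[frames], traj_20min.y[frames], bins=16, range=[[0, 80], [0, 80]]
        )
        rate = np.where(occ > 0, ev / np.maximum(occ, 1), 0.0)
        i, j = np.unravel_index(np.argmax(rate), rate.shape)
        peak_xy = ((i + 0.5) * 5.0, (j + 0.5) * 5.0)
        assert np.hypot(peak_xy[0] - 40.0, peak_xy[1] - 40.0) <= 5.0

    def test_event_count_scales_with_peak_rate(self, arena):
        traj = syn.simulate_trajectory(arena, 300.0, seed=5)
        base = syn.SyntheticCellSpec(
            cell_id=0, anatomical_centroid=(0, 0),
            field_centroids=[(40.0, 40.0)], peak_event_rate=1.0,
        )
        double = syn.SyntheticCellSpec(
            cell_id=0, anatomical_centroid=(0, 0),
            field_centroids=[(40.0, 40.0)], peak_event_rate=2.0,
        )
        n1 = np.mean([
            syn.generate_events(base, traj, noise_rate=0.0, seed=i).n_events
            for i in range(50)
        ])
        n2 = np.mean([
            syn.generate_events(double, traj, noise_rate=0.0, seed=1000 + i).n_events
            for i in range(50)
        ])
        assert 1.8 < n2 / n1 < 2.2

    def test_event_times_within_session(self, place_cell_recording, traj_20min):
        assert np.all(place_cell_recording.events_t >= traj_20min.t[0])
        assert np.all(place_cell_recording.events_t <= traj_20min.t[-1])

    def test_determinism(self, traj_20min, population_60):
        a = syn.generate_events(population_60[1], traj_20min, seed=9)
        b = syn.generate_events(population_60[1], traj_20min, seed=9)
        assert np.array_equal(a.events_t, b.events_t)
        assert np.array_equal(a.dff, b.dff)


class TestRemappingPair:
    def test_preserved_mode_keeps_fields(self, population_60):
        a, b = syn.generate_remapping_pair(population_60, "preserved")
        for ca, cb in zip(a, b):
            assert ca.field_centroids == cb.field_centroids
            assert ca.active == cb.active

    def test_orthogonal_mode_decorrelates_maps(self, arena, fov, population_60):
        """Median same-cell map correlation across an orthogonal pair sits
        at the random-pair baseline, far from 1."""
        a, b = syn.generate_remapping_pair(population_60, "orthogonal", seed=3)
        maps_a = np.array([syn.expected_rate_map(c, arena).ravel() for c in a])
        maps_b = np.array([syn.expected_rate_map(c, arena).ravel() for c in b])
        n = len(a)
        same = [np.corrcoef(maps_a[i], maps_b[i])[0, 1] for i in range(n)]
        rng = np.random.default_rng(0)
        rand = [
            np.corrcoef(maps_a[i], maps_b[rng.choice([j for j in range(n) if j != i])])[0, 1]
            for i in range(n)
        ]
        same_med, rand_med = np.nanmedian(same), np.nanmedian(rand)
        assert same_med < 0.3
        assert abs(same_med - rand_med) < 0.2

    def test_unknown_mode_rejected(self, population_60):
        with pytest.raises(ParameterError):
            syn.generate_remapping_pair(population_60, "sideways")


class TestObjectSession:
    def test_zero_fraction_changes_nothing(self, population_60):
        out = syn.generate_object_session(population_60, (40.0, 40.0), 0.0, seed=0)
        for a, b in zip(population_60, out):
            assert a.field_centroids == b.field_centroids
            assert b.object_vector is None

    def test_object_cells_follow_the_object(self, arena, population_60):
        out = syn.generate_object_session(population_60, (30.0, 40.0), 1.0, seed=1)
        m1 = syn.expected_rate_map(out[0], arena, object_xy=(30.0, 40.0))
        m2 = syn.expected_rate_map(out[0], arena, object_xy=(50.0, 40.0))
        # the object bump shifts by exactly (20, 0) cm = 8 bins in x
        diff1 = m1 - syn.expected_rate_map(population_60[0], arena)
        diff2 = m2 - syn.expected_rate_map(population_60[0], arena)
        i1 = np.array(np.unravel_index(np.argmax(diff1), diff1.shape))
        i2 = np.array(np.unravel_index(np.argmax(diff2), diff2.shape))
        shift = (i2 - i1) * 2.5
        assert abs(shift[0] - 20.0) <= 2.5 and abs(shift[1]) <= 2.5

    def test_uniform_vectors_pass_rayleigh(self, arena, fov):
        from placetopo.objectcells import rayleigh_uniformity

        cells = syn.place_field_population(400, arena, fov, 1.0, seed=2)
        out = syn.generate_object_session(cells, (40.0, 40.0), 1.0, seed=3)
        angles = np.array([c.object_vector[1] for c in out])
        _, p = rayleigh_uniformity(angles)
        assert p > 0.05

    def test_object_outside_arena_rejected(self, population_60):
        with pytest.raises(ParameterError):
            syn.generate_object_session(population_60, (90.0, 40.0), 0.1)
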