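"""Tuning-map construction, field detection, spatial information."""

import numpy as np
import pytest

from placetopo import synthetic as syn
from placetopo import tuning as tn
from placetopo.core import DataError, DegenerateInputError, ParameterError, Trajectory


def two_bin_world():
    """12 s at 1 Hz: 6 s in bin (0-2.5 cm), 6 s in a far bin."""
    t = np.arange(12.0)
    x = np.where(t < 6, 1.0, 50.0)
    y = np.full(12, 1.0)
    return Trajectory(t=t, x=x, y=y)


class TestSpeedFilter:
    def test_vmin_zero_is_identity(self, traj_20min):
        fk, ek = tn.speed_filter(traj_20min, np.array([1.0, 2.0]), 0.0)
        assert fk.all() and ek.all()

    def test_stationary_epoch_removed(self):
        t = np.arange(0, 40, 1 / 15)
        x = np.concatenate([np.linspace(0, 60, 150), np.full(300, 60.0),
                            np.linspace(60, 20, t.size - 450)])
        y = np.full(t.size, 40.0)
        traj = Trajectory(t=t, x=x, y=y)
        fk, _ = tn.speed_filter(traj, np.array([]), 2.0)
        # the plateau in the middle is excluded
        assert fk[200:400].sum() == 0
        assert fk[:100].mean() > 0.9

    def test_all_below_threshold_raises(self):
        t = np.arange(0, 100, 1 / 15)
        traj = Trajectory(t=t, x=np.full(t.size, 1.0), y=np.full(t.size, 1.0))
        with pytest.raises(DegenerateInputError):
            tn.speed_filter(traj, np.array([]), 2.0)


class TestTuningMap:
    def test_grid_shape_from_arena_and_bin(self, traj_20min, arena):
        m = tn.compute_tuning_map(traj_20min, np.array([]), np.array([]), arena)
        assert m.rate.shape == (32, 32)

    def test_no_events_gives_zero_rate(self, traj_20min, arena):
        m = tn.compute_tuning_map(traj_20min, np.array([]), np.array([]), arena)
        assert np.nanmax(m.rate) == 0.0

    def test_two_bin_rate_arithmetic(self):
        traj = two_bin_world()
        events_t = np.array([0.5, 2.5, 4.5])
        m = tn.compute_tuning_map(
            traj, events_t, np.ones(3), syn.ArenaSpec(), smoothing_sigma=0.0, v_min=0.0
        )
        assert m.raw_rate[0, 0] == pytest.approx(0.5)
        assert m.raw_rate[20, 0] == pytest.approx(0.0)

    def test_rate_mass_conservation_presmoothing(self, traj_20min, arena, place_cell_recording):
        rec = place_cell_recording
        m = tn.compute_tuning_map(traj_20min, rec.events_t, rec.events_amp, arena, v_min=0.0)
        total = np.nansum(m.raw_rate * m.occupancy)
        assert total == pytest.approx(rec.events_amp.sum(), rel=1e-9)

    def test_smoothing_preserves_mass_on_full_grid(self):
        rng = np.random.default_rng(0)
        raw = rng.random((32, 32))
        mask = np.ones((32, 32), bool)
        sm = tn.smooth_masked(raw, mask, 2.5)
        assert sm.sum() == pytest.approx(raw.sum(), rel=1e-6)

    def test_rotation_equivariance(self, arena):
        rng = np.random.default_rng(1)
        t = np.arange(0, 400, 1 / 15)
        x = rng.uniform(0, 80, t.size)
        y = rng.uniform(0, 80, t.size)
        traj = Trajectory(t=t, x=x, y=y)
        # rotate 90° CCW about the arena center: (x, y) -> (side - y, x)
        traj_rot = Trajectory(t=t, x=80.0 - y, y=x)
        ev_t = t[rng.choice(t.size, 200, replace=False)]
        amp = np.ones(200)
        m = tn.compute_tuning_map(traj, ev_t, amp, arena, v_min=0.0)
        m_rot = tn.compute_tuning_map(traj_rot, ev_t, amp, arena, v_min=0.0)
        # (x, y) -> (side - y, x) maps bin (i, j) -> (N-1-j, i) == rot90(·, 1)
        np.testing.assert_allclose(
            np.nan_to_num(m_rot.rate), np.nan_to_num(np.rot90(m.rate, k=1)), atol=1e-9
        )

    def test_zero_occupancy_raises(self, arena):
        t = np.arange(0, 100, 1 / 15)
        traj = Trajectory(t=t, x=np.full(t.size, 1.0), y=np.full(t.size, 1.0))
        with pytest.raises(DegenerateInputError):
            tn.compute_tuning_map(traj, np.array([]), np.array([]), arena, v_min=2.0)


class TestObjectMap:
    def test_single_hot_bin_construction(self):
        t = np.arange(0, 200, 1.0)
        # animal due east of the object at 10 cm for all samples
        traj = Trajectory(t=t, x=np.full(t.size, 50.0), y=np.full(t.size, 40.0))
        ev_t = t[10:50].astype(float)
        m = tn.compute_object_map(
            traj, ev_t, np.ones(ev_t.size), (40.0, 40.0),
            smoothing_sigma=0.0, v_min=0.0,
        )
        hot = np.argwhere(np.nan_to_num(m.rate) > 0)
        assert len(hot) == 1
        i, j = hot[0]
        assert (i + 0.5) * m.dist_bin_size == pytest.approx(11.0, abs=2.0)
        assert j == 0  # angle bin containing 0°

    def test_uniform_events_give_flat_map(self, arena):
        rng = np.random.default_rng(2)
        t = np.arange(0, 3000, 1 / 15)
        traj = Trajectory(t=t, x=rng.uniform(0, 80, t.size), y=rng.uniform(0, 80, t.size))
        ev_t = np.sort(rng.choice(t, 20000, replace=False))
        m = tn.compute_object_map(
            traj, ev_t, np.ones(ev_t.size), (40.0, 40.0), v_min=0.0, max_distance=40.0
        )
        vals = m.rate[m.visited_mask & (m.occupancy > 5.0)]
        assert np.std(vals) / np.mean(vals) < 0.5

    def test_corner_object_far_bins_empty(self):
        t = np.arange(0, 500, 1.0)
        rng = np.random.default_rng(3)
        traj = Trajectory(t=t, x=rng.uniform(0, 80, t.size), y=rng.uniform(0, 80, t.size))
        m = tn.compute_object_map(
            traj, np.array([]), np.array([]), (0.0, 0.0), v_min=0.0
        )
        max_possible = 80.0 * np.sqrt(2.0)
        far = int(np.ceil(max_possible / m.dist_bin_size))
        assert not m.visited_mask[far:].any()


class TestMapCorrelation:
    def test_self_correlation_is_one(self, traj_20min, arena, place_cell_recording):
        rec = place_cell_recording
        m = tn.compute_tuning_map(traj_20min, rec.events_t, rec.events_amp, arena)
        assert tn.map_correlation(m, m) == pytest.approx(1.0)

    def test_shuffled_map_uncorrelated(self, traj_20min, arena, place_cell_recording):
        rec = place_cell_recording
        m = tn.compute_tuning_map(traj_20min, rec.events_t, rec.events_amp, arena)
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(50):
            shuf = tn.TuningMap(
                rate=rng.permutation(np.nan_to_num(m.rate).ravel()).reshape(m.rate.shape),
                occupancy=m.occupancy, visited_mask=np.ones_like(m.visited_mask),
                bin_size=m.bin_size, smoothing_sigma=m.smoothing_sigma,
            )
            full = tn.TuningMap(
                rate=np.nan_to_num(m.rate), occupancy=m.occupancy,
                visited_mask=np.ones_like(m.visited_mask),
                bin_size=m.bin_size, smoothing_sigma=m.smoothing_sigma,
            )
            rs.append(tn.map_correlation(full, shuf))
        assert abs(np.mean(rs)) < 0.05

    def test_disjoint_fields_anticorrelated(self, arena):
        c1 = syn.SyntheticCellSpec(0, (0, 0), [(20.0, 20.0)])
        c2 = syn.SyntheticCellSpec(1, (0, 0), [(60.0, 60.0)])
        m1 = syn.expected_rate_map(c1, arena)
        m2 = syn.expected_rate_map(c2, arena)
        mask = np.ones_like(m1, bool)
        t1 = tn.TuningMap(m1, np.ones_like(m1), mask, 2.5, 0.0)
        t2 = tn.TuningMap(m2, np.ones_like(m2), mask, 2.5, 0.0)
        assert tn.map_correlation(t1, t2) < 0

    def test_disjoint_masks_raise(self):
        mask1 = np.zeros((4, 4), bool); mask1[:2] = True
        mask2 = np.zeros((4, 4), bool); mask2[2:] = True
        m1 = tn.TuningMap(np.ones((4, 4)), np.ones((4, 4)), mask1, 2.5, 0.0)
        m2 = tn.TuningMap(np.ones((4, 4)), np.ones((4, 4)), mask2, 2.5, 0.0)
        with pytest.raises(DataError):
            tn.map_correlation(m1, m2)


class TestFields:
    def _map_from_rate(self, rate):
        mask = np.ones_like(rate, bool)
        return tn.TuningMap(rate, np.ones_like(rate), mask, 2.5, 0.0)

    def test_single_bump_centroid(self, arena):
        cell = syn.SyntheticCellSpec(0, (0, 0), [(40.0, 40.0)])
        m = self._map_from_rate(syn.expected_rate_map(cell, arena))
        fields = tn.detect_fields(m)
        assert len(fields) == 1
        cx, cy = fields[0].centroid
        assert abs(cx - 40.0) <= 2.5 and abs(cy - 40.0) <= 2.5

    def test_two_equal_bumps_tie_rule(self, arena):
        cell = syn.SyntheticCellSpec(0, (0, 0), [(20.0, 20.0), (60.0, 60.0)])
        m = self._map_from_rate(syn.expected_rate_map(cell, arena))
        fields = tn.detect_fields(m)
        assert len(fields) == 2
        # equal peaks and areas: main field resolved to the lowest (row, col)
        mf = tn.main_field(fields)
        assert mf.centroid[0] < 40.0

    def test_uniform_map_has_no_fields(self):
        m = self._map_from_rate(np.ones((32, 32)))
        assert tn.detect_fields(m, threshold_fraction=0.2) == []

    def test_all_zero_map_empty(self):
        m = self._map_from_rate(np.zeros((32, 32)))
        assert tn.detect_fields(m) == []


class TestSpatialInformation:
    def _map(self, rate, occ=None):
        occ = np.ones_like(rate) if occ is None else occ
        return tn.TuningMap(rate, occ, occ > 0, 2.5, 0.0)

    def test_uniform_map_zero_bits(self):
        assert tn.spatial_information(self._map(np.full((8, 8), 3.0))) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_one_hot_map_log2_n(self, n):
        side = int(np.sqrt(n))
        rate = np.zeros((side, side))
        rate[0, 0] = 2.0
        assert tn.spatial_information(self._map(rate)) == pytest.approx(np.log2(n))

    def test_four_bin_example(self):
        rate = np.array([[2.0, 0.0], [0.0, 0.0]])
        assert tn.spatial_information(self._map(rate)) == pytest.approx(2.0)

    def test_zero_mean_rate_raises(self):
        with pytest.raises(DegenerateInputError):
            tn.spatial_information(self._map(np.zeros((4, 4))))
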