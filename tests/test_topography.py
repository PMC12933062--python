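"""The clustering battery: pair tables, MI, binned similarity with
size-matched controls, bootstrap CIs, Moran's I, profiles, Cliff's
delta, nearest neighbors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placetopo import topography as tp
from placetopo.core import DataError, DegenerateInputError, ParameterError


class TestPairTable:
    def test_pair_count(self):
        anat = np.array([[0, 0], [10, 0], [0, 10]])
        fields = np.array([[0, 0], [1, 1], [2, 2]])
        t = tp.build_pair_table(anat, fields)
        assert len(t) == 3  # n(n-1)/2

    def test_fov_diagonal_distance(self):
        anat = np.array([[0.0, 0.0], [350.0, 350.0]])
        t = tp.build_pair_table(anat, np.zeros((2, 2)))
        assert t["anatomical_distance"].iloc[0] == pytest.approx(350 * np.sqrt(2))

    def test_no_self_pairs(self):
        anat = np.array([[0, 0], [10, 10]])
        t = tp.build_pair_table(anat, np.zeros((2, 2)))
        assert not (t["cell_i"] == t["cell_j"]).any()

    def test_single_cell_empty(self):
        t = tp.build_pair_table(np.array([[0, 0]]), np.zeros((1, 2)))
        assert len(t) == 0


class TestMutualInformation:
    def test_deterministic_relation_is_large(self):
        x = np.random.default_rng(0).uniform(0, 1, 1000)
        assert tp.mutual_information_continuous(x, x) > 2.0

    def test_independent_is_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(0, 1, 10_000), rng.uniform(0, 1, 10_000)
        assert tp.mutual_information_continuous(x, y) < 0.01

    def test_constant_input_is_degenerate_zero(self):
        x = np.zeros(200)
        y = np.random.default_rng(2).normal(size=200)
        assert tp.mutual_information_continuous(x, y) == 0.0

    def test_binned_estimator_agrees_on_gaussian(self):
        rng = np.random.default_rng(3)
        rho = 0.6
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 20_000)
        expect = -0.5 * np.log(1 - rho**2)
        knn = tp.mutual_information_continuous(z[:, 0], z[:, 1])
        binned = tp.mutual_information_binned(z[:, 0], z[:, 1])
        assert knn == pytest.approx(expect, abs=0.02)
        assert binned == pytest.approx(expect, abs=0.05)


class TestWithinBin:
    def _stat(self, n, value=0.5):
        s = np.full((n, n), value)
        np.fill_diagonal(s, 1.0)
        return s

    def test_three_cells_mean_of_three_pairs(self):
        anat = np.array([[5.0, 5.0], [20.0, 5.0], [5.0, 20.0]])
        stat = np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.3], [0.2, 0.3, 1.0]])
        df = tp.within_bin_similarity(anat, stat, exclusion=0.0)
        assert len(df) == 1
        assert df["mean_stat"].iloc[0] == pytest.approx(np.mean([0.1, 0.2, 0.3]))

    def test_sub15um_pair_excluded(self):
        anat = np.array([[5.0, 5.0], [10.0, 5.0], [5.0, 30.0]])  # first two 5 µm apart
        stat = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]])
        df = tp.within_bin_similarity(anat, stat, exclusion=15.0)
        assert df["mean_stat"].iloc[0] == pytest.approx(np.mean([0.2, 0.3]))

    def test_two_cell_bin_skipped(self):
        anat = np.array([[5.0, 5.0], [20.0, 20.0]])
        df = tp.within_bin_similarity(anat, self._stat(2), exclusion=0.0)
        assert len(df) == 0

    def test_constant_statistic_matches_control(self):
        rng = np.random.default_rng(4)
        anat = rng.uniform(0, 350, (40, 2))
        stat = self._stat(40, 0.7)
        obs = tp.within_bin_similarity(anat, stat, exclusion=0.0)
        ctrl = tp.size_matched_control(
            anat, stat, obs["n_cells"].tolist(), n_iter=10, exclusion=0.0, seed=0
        )
        assert np.allclose(ctrl, 0.7)
        assert np.allclose(obs["mean_stat"], 0.7)

    def test_oversized_bin_rejected(self):
        anat = np.random.default_rng(5).uniform(0, 350, (5, 2))
        with pytest.raises(ParameterError):
            tp.size_matched_control(anat, self._stat(5), [10], seed=0)


class TestBootstrap:
    def test_constant_values(self):
        med, lo, hi = tp.bootstrap_median_ci(np.full(20, 3.3), n_boot=100, seed=0)
        assert med == lo == hi == 3.3

    def test_ci_brackets_median(self):
        med, lo, hi = tp.bootstrap_median_ci(
            np.array([1.0, 2, 3, 4, 5]), n_boot=100_000, seed=1
        )
        assert med == 3.0 and lo <= 3.0 <= hi

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (50, 200, 800):
            vals = rng.normal(size=n)
            _, lo, hi = tp.bootstrap_median_ci(vals, n_boot=3000, seed=3)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_99_contains_95_on_same_draws(self):
        vals = np.random.default_rng(6).normal(size=100)
        _, lo99, hi99 = tp.bootstrap_median_ci(vals, n_boot=5000, level=99, seed=7)
        _, lo95, hi95 = tp.bootstrap_median_ci(vals, n_boot=5000, level=95, seed=7)
        assert lo99 <= lo95 and hi95 <= hi99

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            tp.bootstrap_median_ci(np.array([1.0]))


class TestMoran:
    def test_checkerboard_is_perfectly_dispersed(self):
        n = 6
        pos = np.array([(i, j) for i in range(n) for j in range(n)], float)
        vals = np.array([(-1.0) ** (i + j) for i in range(n) for j in range(n)])
        # rook contiguity, row-standardized
        d = np.abs(pos[:, None, :] - pos[None, :, :]).sum(-1)
        w = (d == 1).astype(float)
        w /= w.sum(1, keepdims=True)
        res = tp.global_morans_i(pos, vals, weights=w, n_perm=50, seed=0)
        assert res.I == pytest.approx(-1.0)

    def test_gradient_is_detected_as_clustered(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 350, (60, 2))
        vals = pos[:, 0] / 350.0 + rng.normal(0, 0.05, 60)
        res = tp.global_morans_i(pos, vals, n_perm=500, seed=2, bin_size=45.0)
        assert res.significant and res.I > res.p95

    def test_zero_variance_rejected(self):
        pos = np.random.default_rng(3).uniform(0, 100, (10, 2))
        with pytest.raises(DegenerateInputError):
            tp.global_morans_i(pos, np.ones(10))

    def test_local_sums_to_global(self):
        """With row-standardized weights and no islands, Σ local_I = n·I."""
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 200, (30, 2))
        vals = rng.normal(size=30)
        w = tp.spatial_weights(pos, cutoff=500.0)
        glob = tp.global_morans_i(pos, vals, weights=w, n_perm=50, seed=5)
        loc = tp.local_morans_i(pos, vals, weights=w, n_perm=50, seed=5)
        assert loc["local_I"].sum() == pytest.approx(30 * glob.I, rel=1e-9)

    def test_isolated_hot_unit_negative_local(self):
        pos = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10], [5, 5],
                        [200, 200], [210, 200], [200, 210]])
        vals = np.array([0.0, 0, 0, 0, 10.0, 0, 0, 0])
        loc = tp.local_morans_i(pos, vals, n_perm=50, seed=6, cutoff=30.0)
        assert loc["local_I"].iloc[4] < 0


class TestProfiles:
    def test_boundary_is_closed(self):
        anat = np.array([[0.0, 0.0], [15.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
        stat = np.full((5, 5), 0.5)
        prof = tp.expanding_circle_profile(
            anat, stat, radii=np.array([15.0]), n_iter=5, n_boot=50, seed=0
        )
        assert prof["n_pairs"].iloc[0] == 1  # the pair at exactly 15 µm

    def test_nonincreasing_radii_rejected(self):
        anat = np.random.default_rng(1).uniform(0, 350, (10, 2))
        with pytest.raises(ParameterError):
            tp.expanding_circle_profile(
                anat, np.ones((10, 10)), radii=np.array([20.0, 15.0])
            )

    def test_null_population_control_inside_ci(self):
        from placetopo import synthetic as syn
        from placetopo.calibration import population_battery

        cells = syn.place_field_population(200, active_fraction=1.0, seed=77)
        res = population_battery(
            cells, syn.ArenaSpec(), syn.FovSpec(), n_perm=200, n_boot=1000, seed=78
        )
        assert tp.profile_control_within_ci(res["profile"]) >= 0.8

    def test_fieldspace_profile_mirrors(self):
        rng = np.random.default_rng(2)
        fields = rng.uniform(0, 80, (50, 2))
        anat = rng.uniform(0, 350, (50, 2))
        prof = tp.fieldspace_profile(fields, anat, n_iter=20, n_boot=500, seed=3)
        assert list(prof["radius"]) == [5.0 * k for k in range(1, 11)]
        assert prof["n_pairs"].is_monotonic_increasing


class TestCliffsDelta:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2, 3])
        assert tp.cliffs_delta(x, x) == 0.0

    def test_fully_separated_is_one(self):
        assert tp.cliffs_delta(np.array([5.0, 6]), np.array([1.0, 2])) == 1.0

    def test_worked_example(self):
        # brute-force over all 9 pairs gives (2 - 5)/9
        assert tp.cliffs_delta(np.array([1.0, 2, 3]), np.array([2.0, 2, 4])) == pytest.approx(-1 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        st.lists(st.floats(-100, 100), min_size=1, max_size=30),
    )
    def test_antisymmetric_and_bounded(self, xs, ys):
        x, y = np.array(xs), np.array(ys)
        d = tp.cliffs_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-tp.cliffs_delta(y, x))

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            tp.cliffs_delta(np.array([]), np.array([1.0]))


class TestNearestNeighbor:
    def test_two_cells_are_mutual_neighbors(self):
        anat = np.array([[0.0, 0.0], [50.0, 0.0], [0, 300], [300, 0], [300, 300],
                         [150, 150], [10, 200], [200, 10]])
        stat = np.random.default_rng(0).uniform(-1, 1, (8, 8))
        stat = (stat + stat.T) / 2
        table, _ = tp.nearest_neighbor_analysis(anat, stat, n_perm=50, seed=1, cutoff=500.0)
        assert table["neighbor_id"].iloc[0] == 1
        assert table["neighbor_id"].iloc[1] == 0

    def test_tie_broken_by_lowest_id(self):
        anat = np.array([[0.0, 0.0], [10.0, 0.0], [-10.0, 0.0], [0, 200],
                         [200, 0], [200, 200], [100, 100], [50, 150]])
        stat = np.zeros((8, 8))
        stat += np.random.default_rng(1).uniform(0, 1, (8, 8))
        stat = (stat + stat.T) / 2
        table, _ = tp.nearest_neighbor_analysis(anat, stat, n_perm=50, seed=2, cutoff=500.0)
        # cell 0 is equidistant (10 µm) from cells 1 and 2 → picks 1
        assert table["neighbor_id"].iloc[0] == 1
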