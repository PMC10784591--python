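import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smlmclust import (
    DensityHistogram,
    FieldBounds,
    Trajectory,
    TrajectorySpec,
    density_around_spots,
    density_difference_summary,
    fit_lifetime,
    logrank_compare,
    masks_from_discs,
    randomize_trajectories,
    residency_durations,
    simulate_trajectories,
    spots_from_trajectories,
)

from conftest import make_table


@pytest.fixture
def one_disc():
    fb = FieldBounds(0, 0, 2000, 2000)
    return masks_from_discs([(1000.0, 1000.0)], 200.0, fb)


def brute_force_durations(traj, clusters):
    """Frame-by-frame point-in-mask scan, one sample at a time."""
    inside = [bool(clusters.contains(x, y)[0] > 0) for x, y in zip(traj.x, traj.y)]
    durations = []
    run = 0
    for k, flag in enumerate(inside + [False]):
        gap_break = k > 0 and k < len(traj.frames) and traj.frames[k] - traj.frames[k - 1] > 1
        if flag and not gap_break:
            run += 1
        else:
            if run:
                durations.append(run * traj.frame_interval_ms)
            run = 1 if flag else 0
    return durations


class TestDurations:
    def test_five_consecutive_frames_give_165_ms(self, one_disc):
        xs = [100, 100, 1000, 1000, 1000, 1000, 1000, 100]
        traj = Trajectory(id="t", frames=np.arange(1, 9), x=xs, y=[1000] * 8)
        d = residency_durations([traj], one_disc)
        np.testing.assert_allclose(d, [5 * 33.0])

    def test_trajectory_never_entering_mask_has_no_events(self, one_disc):
        traj = Trajectory(id="t", frames=[1, 2, 3], x=[10, 20, 30], y=[10, 10, 10])
        assert len(residency_durations([traj], one_disc)) == 0

    def test_runs_touching_trajectory_ends_are_censored(self, one_disc):
        traj = Trajectory(
            id="t", frames=np.arange(1, 6),
            x=[1000, 1000, 100, 1000, 1000], y=[1000] * 5,
        )
        d, cens = residency_durations([traj], one_disc, return_censoring=True)
        assert len(d) == 2
        assert cens.tolist() == [True, True]

    def test_frame_gap_splits_a_run(self, one_disc):
        traj = Trajectory(
            id="t", frames=[1, 2, 3, 7, 8, 9, 10],
            x=[100, 1000, 1000, 1000, 1000, 100, 100], y=[1000] * 7,
        )
        d, cens = residency_durations([traj], one_disc, return_censoring=True)
        np.testing.assert_allclose(sorted(d), [2 * 33.0, 2 * 33.0])
        assert not cens.any()

    def test_matches_bruteforce_scan_on_simulated_trajectories(self):
        fb = FieldBounds(0, 0, 4000, 4000)
        masks = masks_from_discs([(1000, 1000), (3000, 3000)], 250.0, fb)
        spec = TrajectorySpec(n_trajectories=50, residency_tau_ms=120.0)
        trajs, _ = simulate_trajectories(spec, masks, seed=40)
        expected = []
        for t in trajs:
            expected.extend(brute_force_durations(t, masks))
        got = residency_durations(trajs, masks)
        np.testing.assert_allclose(np.sort(got), np.sort(expected))

    def test_extracted_durations_match_ground_truth_within_one_frame(self):
        fb = FieldBounds(0, 0, 4000, 4000)
        masks = masks_from_discs([(1000, 1000), (3000, 3000)], 250.0, fb)
        spec = TrajectorySpec(n_trajectories=100, residency_tau_ms=150.0)
        trajs, truth = simulate_trajectories(spec, masks, seed=41)
        durations = residency_durations(trajs, masks)
        # every dwell with at least one in-mask sample becomes one run,
        # in recording order, with exactly the realized sample count
        realized = truth.loc[truth["realized_frames"] >= 1, "realized_frames"]
        np.testing.assert_allclose(durations, realized.to_numpy() * 33.0)
        # realized run length is ceil(dwell / frame): within one frame of
        # the continuous ground-truth dwell for uncensored events
        ok = (~truth["censored"]) & (truth["realized_frames"] >= 1)
        diff = truth.loc[ok, "realized_frames"] * 33.0 - truth.loc[ok, "dwell_ms"]
        assert np.all(diff > -1e-9) and np.all(diff <= 33.0 + 1e-9)

    def test_empty_mask_warns(self, one_disc):
        empty = masks_from_discs(
            np.empty((0, 2)), 100.0, FieldBounds(0, 0, 100, 100)
        )
        traj = Trajectory(id="t", frames=[1], x=[50.0], y=[50.0])
        with pytest.warns(UserWarning):
            d = residency_durations([traj], empty)
        assert len(d) == 0


class TestLifetimeFit:
    def test_discretized_exponential_dwells_recover_tau(self, rng):
        dwell = rng.exponential(150.0, 2000)
        realized = np.ceil(dwell / 33.0).clip(min=1) * 33.0
        res = fit_lifetime(realized, frame_interval_ms=33.0)
        assert abs(res.tau_ms - 150.0) / 150.0 < 0.10
        assert res.tau_ci_ms > 0

    def test_short_dwells_still_resolvable(self, rng):
        dwell = rng.exponential(74.0, 2000)
        realized = np.ceil(dwell / 33.0).clip(min=1) * 33.0
        res = fit_lifetime(realized, frame_interval_ms=33.0)
        assert abs(res.tau_ms - 74.0) / 74.0 < 0.15

    def test_underpowered_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime(np.full(10, 33.0))

    def test_constant_durations_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime(np.full(100, 33.0))


class TestLogRank:
    def test_identical_samples_not_significant(self, rng):
        d = rng.exponential(150.0, 200)
        stat, p = logrank_compare(d, d)
        assert p > 0.99

    def test_distinct_lifetimes_detected(self, rng):
        a = rng.exponential(150.0, 300)
        b = rng.exponential(74.0, 300)
        _, p = logrank_compare(a, b)
        assert p < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            logrank_compare(np.array([]), np.array([1.0]))


class TestRandomization:
    def test_internal_displacements_preserved_exactly(self, rng):
        fb = FieldBounds(0, 0, 5000, 5000)
        trajs = [
            Trajectory(
                id=f"t{i}", frames=np.arange(1, 11),
                x=2500 + np.cumsum(rng.normal(0, 50, 10)),
                y=2500 + np.cumsum(rng.normal(0, 50, 10)),
            )
            for i in range(20)
        ]
        rand = randomize_trajectories(trajs, fb, seed=5)
        for t, r in zip(trajs, rand):
            np.testing.assert_allclose(np.diff(r.x), np.diff(t.x), atol=1e-9)
            np.testing.assert_allclose(np.diff(r.y), np.diff(t.y), atol=1e-9)

    def test_single_sample_placement_uniform_by_chisquare(self):
        fb = FieldBounds(0, 0, 2000, 2000)
        traj = Trajectory(id="t", frames=[1], x=[1000.0], y=[1000.0])
        rand = randomize_trajectories([traj] * 10000, fb, seed=6)
        xs = np.array([r.x[0] for r in rand])
        ys = np.array([r.y[0] for r in rand])
        counts, _, _ = np.histogram2d(xs, ys, bins=[10, 10], range=[[0, 2000], [0, 2000]])
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        # 99 degrees of freedom
        assert chi2 < sps.chi2(99).ppf(0.999)

    def test_oversized_trajectory_raises(self):
        fb = FieldBounds(0, 0, 100, 100)
        traj = Trajectory(id="t", frames=[1, 2], x=[0.0, 500.0], y=[0.0, 0.0])
        with pytest.raises(RuntimeError):
            randomize_trajectories([traj], fb, seed=7, max_retries=50)


class TestDensityAroundSpots:
    def test_no_localizations_put_all_mass_at_zero(self):
        fb = FieldBounds(0, 0, 1000, 1000)
        table = make_table(x=[1.0], y=[1.0], field_bounds=fb)
        table = table.with_df(table.df.iloc[:0])
        table.field_bounds = fb
        spots = pd.DataFrame({"x": [500.0], "y": [500.0]})
        h = density_around_spots(table, spots, observation_period_s=1.0,
                                 observation_area_um2=1.0)
        assert h.frequency[0] > 0
        assert h.frequency[1:].sum() == 0

    def test_multiplicity_division_gives_molecule_estimate(self, rng):
        fb = FieldBounds(0, 0, 1000, 1000)
        # 27 localizations tightly around the spot: 27 / 2.7 = 10 molecules
        table = make_table(
            x=500 + rng.uniform(-50, 50, 27), y=500 + rng.uniform(-50, 50, 27),
            field_bounds=fb,
        )
        spots = pd.DataFrame({"x": [500.0], "y": [500.0]})
        h = density_around_spots(
            table, spots, radius_nm=100.0, multiplicity=2.7,
            observation_period_s=2.0, observation_area_um2=5.0,
        )
        k = np.nonzero(h.frequency)[0]
        assert len(k) == 1
        assert h.bin_edges[k[0]] == 10.0  # estimate falls in the [10, 11) bin
        assert h.frequency[k[0]] == pytest.approx(1.0 / (2.0 * 5.0))

    def test_small_radius_warns(self):
        fb = FieldBounds(0, 0, 1000, 1000)
        table = make_table(x=[500.0], y=[500.0], field_bounds=fb)
        spots = pd.DataFrame({"x": [500.0], "y": [500.0]})
        with pytest.warns(UserWarning, match="100 nm"):
            density_around_spots(table, spots, radius_nm=50.0,
                                 observation_period_s=1.0, observation_area_um2=1.0)


class TestDifferenceSummary:
    @staticmethod
    def hist(freq):
        freq = np.asarray(freq, float)
        return DensityHistogram(
            bin_edges=np.arange(len(freq) + 1, dtype=float) - 0.5,
            frequency=freq,
            observation_period_s=1.0,
            observation_area_um2=1.0,
        )

    def test_worked_arithmetic_example(self):
        obs = self.hist([0, 2, 3, 0, 1])
        ran = self.hist([1, 0, 0, 1, 0])
        out = density_difference_summary(obs, ran)
        np.testing.assert_allclose(out["difference"], [-1, 2, 3, -1, 1])
        assert out["positive_run"] == (1, 3)
        assert out["positive_run_sum"] == pytest.approx(5.0)
        assert out["positive_run_mean_count"] == pytest.approx((1 * 2 + 2 * 3) / 5.0)

    def test_equal_histograms_have_absent_summary(self):
        obs = self.hist([1, 2, 3])
        with pytest.warns(UserWarning):
            out = density_difference_summary(obs, obs)
        assert out["positive_run_sum"] is None

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            density_difference_summary(self.hist([1, 2]), self.hist([1, 2, 3]))

    def test_spots_on_clusters_enrich_high_count_bins(self, rng):
        fb = FieldBounds(0, 0, 3000, 3000)
        masks = masks_from_discs([(1000, 1000), (2000, 2000)], 150.0, fb)
        # dense localizations inside the two clusters
        n = 400
        cl = rng.integers(0, 2, n)
        cx = np.where(cl == 0, 1000, 2000)
        table = make_table(
            x=cx + rng.uniform(-100, 100, n), y=cx + rng.uniform(-100, 100, n),
            field_bounds=fb,
        )
        on_spots = pd.DataFrame(
            {"x": cx[:100] + rng.uniform(-50, 50, 100),
             "y": cx[:100] + rng.uniform(-50, 50, 100)}
        )
        off_spots = pd.DataFrame(
            {"x": rng.uniform(0, 3000, 100), "y": rng.uniform(0, 3000, 100)}
        )
        kw = dict(radius_nm=100.0, multiplicity=2.7,
                  observation_period_s=1.0, observation_area_um2=9.0, n_bins=80)
        obs = density_around_spots(table, on_spots, **kw)
        ran = density_around_spots(table, off_spots, **kw)
        out = density_difference_summary(obs, ran)
        assert out["positive_run_sum"] is not None and out["positive_run_sum"] > 0
        assert out["positive_run_mean_count"] > 1.0


class TestSpotsFromTrajectories:
    def test_all_samples_exported(self):
        trajs = [
            Trajectory(id="a", frames=[1, 2], x=[0.0, 1.0], y=[0.0, 1.0]),
            Trajectory(id="b", frames=[5], x=[2.0], y=[3.0]),
        ]
        spots = spots_from_trajectories(trajs)
        assert len(spots) == 3
        assert set(spots["id"]) == {"a", "b"}
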