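import numpy as np
import pytest

from smlmclust import (
    ClusterSpec,
    FieldBounds,
    cluster_statistics,
    compute_kde_map,
    filter_uncertainties,
    grid_centers,
    otsu_threshold,
    segment_clusters,
    simulate_cluster_field,
)
from smlmclust.segmentation import ClusterSet, KERNEL_TRUNCATION_SD

from conftest import make_table


def kde_oracle(table, A, kde_map, pixels):
    """Brute-force kernel sum at the given (row, col) pixels."""
    xc, yc = kde_map.pixel_centers()
    out = []
    for i, j in pixels:
        px, py = xc[j], yc[i]
        total = 0.0
        for xi, yi, ui in zip(table.x, table.y, table.uncertainty):
            s = A * ui
            r = KERNEL_TRUNCATION_SD * s
            # same half-open truncation window as the implementation
            if not (xi - r <= px < xi + r and yi - r <= py < yi + r):
                continue
            total += np.exp(
                -((px - xi) ** 2 + (py - yi) ** 2) / (2 * s**2)
            ) / (2 * np.pi * s**2)
        out.append(total / len(table))
    return np.array(out)


class TestUncertaintyFilter:
    def test_full_band_is_identity(self, rng):
        table = make_table(
            x=rng.uniform(0, 1000, 50), y=rng.uniform(0, 1000, 50),
            uncertainty=rng.uniform(10, 30, 50),
        )
        assert len(filter_uncertainties(table, 0, 100)) == 50

    def test_percentile_band_removes_expected_fraction(self, rng):
        table = make_table(
            x=rng.uniform(0, 1000, 1000), y=rng.uniform(0, 1000, 1000),
            uncertainty=rng.uniform(10, 30, 1000),
        )
        kept = len(filter_uncertainties(table, 1, 99))
        assert 970 <= kept <= 990

    def test_constant_uncertainties_all_retained(self, rng):
        table = make_table(x=rng.uniform(0, 100, 200), y=rng.uniform(0, 100, 200))
        assert len(filter_uncertainties(table, 1, 99)) == 200

    def test_invalid_band_rejected(self, rng):
        table = make_table(x=[0.0], y=[0.0])
        with pytest.raises(ValueError):
            filter_uncertainties(table, 50, 40)


class TestKDEMap:
    def test_single_kernel_peaks_at_its_pixel_and_normalizes(self):
        fb = FieldBounds(0, 0, 2000, 2000)
        table = make_table(x=[1005.0], y=[865.0], field_bounds=fb)
        kde = compute_kde_map(table)
        i, j = np.unravel_index(np.argmax(kde.grid), kde.grid.shape)
        assert (i, j) == (int(865 / 20), int(1005 / 20))
        assert kde.grid.sum() * kde.pixel_area_nm2 == pytest.approx(1.0, abs=0.01)

    def test_duplicate_localizations_leave_average_unchanged(self):
        fb = FieldBounds(0, 0, 2000, 2000)
        one = make_table(x=[700.0], y=[900.0], field_bounds=fb)
        two = make_table(x=[700.0, 700.0], y=[900.0, 900.0], field_bounds=fb)
        np.testing.assert_allclose(
            compute_kde_map(one).grid, compute_kde_map(two).grid, rtol=1e-12
        )

    def test_map_matches_bruteforce_kernel_sum(self, rng):
        fb = FieldBounds(0, 0, 3000, 3000)
        n = 300
        table = make_table(
            x=rng.uniform(500, 2500, n), y=rng.uniform(500, 2500, n),
            uncertainty=rng.uniform(15, 25, n), field_bounds=fb,
        )
        kde = compute_kde_map(table, A=6.0)
        pixels = [
            (rng.integers(0, kde.grid.shape[0]), rng.integers(0, kde.grid.shape[1]))
            for _ in range(25)
        ]
        expected = kde_oracle(table, 6.0, kde, pixels)
        got = np.array([kde.grid[i, j] for i, j in pixels])
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-30)

    def test_empty_table_rejected(self):
        table = make_table(x=[1.0], y=[1.0])
        with pytest.raises(ValueError):
            compute_kde_map(table.with_df(table.df.iloc[:0]))


class TestOtsu:
    def test_bimodal_map_threshold_separates_modes(self, rng):
        values = np.concatenate([np.full(500, 0.1), np.full(500, 0.9)])
        values += rng.normal(0, 1e-6, 1000)
        theta = otsu_threshold(values)
        assert 0.1 < theta <= 0.9

    def test_matches_exhaustive_search_oracle(self, rng):
        values = np.concatenate(
            [rng.normal(0.2, 0.05, 4000), rng.normal(0.8, 0.1, 2000)]
        )
        theta = otsu_threshold(values)
        # independent exhaustive search over the same 256 candidate edges
        edges = np.histogram_bin_edges(values, bins=256)
        best_t, best_v = None, -1.0
        for t in edges[1:-1]:
            lo, hi = values[values < t], values[values >= t]
            if len(lo) == 0 or len(hi) == 0:
                continue
            w0, w1 = len(lo) / len(values), len(hi) / len(values)
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        bin_width = edges[1] - edges[0]
        assert abs(theta - best_t) <= bin_width + 1e-12

    def test_agrees_with_reference_otsu_within_one_bin(self, rng):
        from skimage.filters import threshold_otsu

        values = np.concatenate(
            [rng.normal(0.1, 0.03, 5000), rng.normal(0.7, 0.15, 3000)]
        )
        theta = otsu_threshold(values)
        ref = threshold_otsu(values, nbins=256)
        bin_width = (values.max() - values.min()) / 256
        assert abs(theta - ref) <= bin_width + 1e-12

    def test_translation_equivariance(self, rng):
        values = rng.normal(0.5, 0.2, 2000)
        t0 = otsu_threshold(values)
        t1 = otsu_threshold(values + 3.7)
        assert t1 - t0 == pytest.approx(3.7, abs=1e-9)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(100, 0.5))


class TestSegmentation:
    @staticmethod
    def small_field(rng, n_clusters=2, mpc=30, spacing=2500.0):
        spec = ClusterSpec(
            centers=grid_centers(n_clusters, spacing_nm=spacing),
            molecules_per_cluster=mpc,
        )
        table, truth = simulate_cluster_field(spec, seed=int(rng.integers(1 << 30)))
        return table, truth, spec

    def test_single_cluster_multiplicity_one_counts_localizations(self):
        fb = FieldBounds(0, 0, 2000, 2000)
        rng = np.random.default_rng(0)
        table = make_table(
            x=1000 + rng.normal(0, 30, 10), y=1000 + rng.normal(0, 30, 10),
            field_bounds=fb,
        )
        kde = compute_kde_map(table)
        cs = segment_clusters(kde, otsu_threshold(kde), 1.0, table)
        assert len(cs) == 1
        assert cs.clusters["corrected_count"].iloc[0] == 10

    def test_separated_clusters_get_distinct_labels_and_counts_conserve(self, rng):
        table, truth, spec = self.small_field(rng)
        kde = compute_kde_map(table)
        theta = otsu_threshold(kde)
        cs = segment_clusters(kde, theta, 2.7, table)
        assert len(cs) == 2
        # conservation: in-mask plus outside equals table size
        assert cs.clusters["localization_count"].sum() + cs.n_outside == len(table)
        # brute-force point-in-mask recount
        labels = cs.contains(table.x, table.y)
        for cid in (1, 2):
            assert (labels == cid).sum() == int(
                cs.clusters.set_index("id").loc[cid, "localization_count"]
            )

    def test_boundary_pixels_touch_background(self, rng):
        table, _, _ = self.small_field(rng, n_clusters=1)
        kde = compute_kde_map(table)
        cs = segment_clusters(kde, otsu_threshold(kde), 2.7, table)
        lm = cs.label_map
        padded = np.pad(lm > 0, 1)
        for bx, by in cs.boundaries[1]:
            j = int((bx - cs.origin_nm[0]) / cs.grid_pixel_nm)
            i = int((by - cs.origin_nm[1]) / cs.grid_pixel_nm)
            neigh = padded[i : i + 3, j : j + 3]
            assert not neigh.all()  # at least one background neighbor

    def test_mask_area_shrinks_as_threshold_rises(self, rng):
        table, _, _ = self.small_field(rng)
        kde = compute_kde_map(table)
        theta = otsu_threshold(kde)
        a1 = (kde.grid >= theta).sum()
        a2 = (kde.grid >= 1.5 * theta).sum()
        assert a2 <= a1

    def test_threshold_above_maximum_yields_empty_set(self, rng):
        table, _, _ = self.small_field(rng, n_clusters=1)
        kde = compute_kde_map(table)
        with pytest.warns(UserWarning):
            cs = segment_clusters(kde, kde.grid.max() * 2, 2.7, table)
        assert len(cs) == 0
        assert cs.n_outside == len(table)


class TestClusterStatistics:
    @staticmethod
    def fake_clusterset(counts):
        import pandas as pd

        df = pd.DataFrame(
            {
                "id": np.arange(1, len(counts) + 1),
                "n_pixels": 10,
                "area_um2": 0.004,
                "localization_count": np.asarray(counts) * 2,
                "corrected_count": counts,
                "centroid_x": 0.0,
                "centroid_y": 0.0,
            }
        )
        return ClusterSet(
            label_map=np.zeros((2, 2), dtype=np.int32),
            grid_pixel_nm=20.0,
            origin_nm=(0.0, 0.0),
            clusters=df,
        )

    def test_mean_per_cluster(self):
        stats = cluster_statistics(self.fake_clusterset([10.0, 20.0, 30.0]))
        assert stats.mean_per_cluster == pytest.approx(20.0)

    def test_large_cluster_density_arithmetic(self):
        stats = cluster_statistics(
            self.fake_clusterset([900.0, 100.0]),
            cell_areas_um2=10.0,
            large_threshold=800.0,
        )
        assert stats.large_cluster_density["cell0"] == pytest.approx(90.0)

    def test_per_cell_means_and_sem(self):
        stats = cluster_statistics(
            {
                "c1": self.fake_clusterset([10.0, 20.0]),
                "c2": self.fake_clusterset([40.0]),
            }
        )
        assert stats.per_cell_means == {"c1": 15.0, "c2": 40.0}
        assert stats.per_cell_mean == pytest.approx(27.5)
        assert stats.mean_per_cluster == pytest.approx(70.0 / 3)

    def test_no_clusters_reports_absent(self):
        with pytest.warns(UserWarning):
            stats = cluster_statistics(self.fake_clusterset([]))
        assert stats.mean_per_cluster is None
        assert stats.n_clusters == 0


class TestCountingRecovery:
    @pytest.mark.parametrize("size,n_clusters", [(10, 60), (52, 40)])
    def test_corrected_counts_unbiased_for_known_cluster_sizes(self, size, n_clusters):
        from smlmclust import BlinkCalibration, KineticModelParams

        params = KineticModelParams(k_d=17.0, k_b=10.0)
        spec = ClusterSpec(
            centers=grid_centers(n_clusters, spacing_nm=2000.0),
            molecules_per_cluster=size,
        )
        table, _ = simulate_cluster_field(spec, params, seed=size)
        kde = compute_kde_map(table)
        cs = segment_clusters(
            kde, otsu_threshold(kde), BlinkCalibration.from_rates(17, 10).multiplicity, table
        )
        assert len(cs) == n_clusters
        counts = cs.clusters["corrected_count"].to_numpy()
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - size) < 3 * se
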