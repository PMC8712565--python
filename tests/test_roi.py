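"""ROI statistics, cluster labeling, Monte-Carlo thresholds and the
repeated-measures comparison, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gccafmri.glm import TMap
from gccafmri.grids import GridSpec, SubjectTimeseries
from gccafmri.roi import (
    cluster_label,
    compare_arms,
    monte_carlo_cluster_threshold,
    rm_anova_two_way,
    roi_extent_and_peak,
    roi_snr,
)


def _roi_volume(grid, where):
    roi = np.zeros(grid.dims, dtype=bool)
    roi[where] = True
    return roi


class TestRoiExtentAndPeak:
    def test_zero_tmap_zero_extent(self, full_grid):
        tmap = TMap(t=np.zeros(full_grid.n_voxels), df=24, grid=full_grid)
        roi = _roi_volume(full_grid, (slice(0, 3), slice(0, 3), slice(0, 2)))
        extent, peak = roi_extent_and_peak(tmap, roi, 0.01)
        assert extent == 0
        assert peak == 0.0

    def test_single_hot_voxel(self, full_grid):
        t = np.zeros(full_grid.n_voxels)
        t[0] = 10.0
        tmap = TMap(t=t, df=24, grid=full_grid)
        roi = _roi_volume(full_grid, (0, 0, 0))
        extent, peak = roi_extent_and_peak(tmap, roi, 0.01)
        assert (extent, peak) == (1, 10.0)

    def test_matches_bruteforce_count(self, full_grid, rng):
        t = rng.standard_normal(full_grid.n_voxels) * 3
        tmap = TMap(t=t, df=24, grid=full_grid)
        roi = _roi_volume(full_grid, (slice(2, 8), slice(1, 6), slice(0, 4)))
        extent, peak = roi_extent_and_peak(tmap, roi, 0.01)
        t_crit = stats.t.ppf(0.99, 24)
        vol_t = full_grid.embed(t)
        count = sum(
            vol_t[i, j, k] > t_crit
            for i in range(10) for j in range(10) for k in range(5)
            if roi[i, j, k]
        )
        assert extent == count
        assert peak == pytest.approx(vol_t[roi].max())

    def test_empty_roi_rejected(self, full_grid):
        tmap = TMap(t=np.zeros(full_grid.n_voxels), df=24, grid=full_grid)
        with pytest.raises(ValueError, match="no masked voxels"):
            roi_extent_and_peak(tmap, np.zeros(full_grid.dims, bool), 0.01)


class TestRoiSnr:
    def test_constant_roi_over_unit_noise(self, full_grid, rng):
        data = np.zeros((full_grid.n_voxels, 50))
        roi = _roi_volume(full_grid, (slice(0, 2), slice(0, 2), slice(0, 2)))
        noise = _roi_volume(full_grid, (slice(5, 9), slice(5, 9), slice(0, 3)))
        data[full_grid.extract(roi)] = 100.0
        series = rng.standard_normal(50)
        series = (series - series.mean()) / series.std(ddof=0)
        data[full_grid.extract(noise)] = series  # identical in every voxel
        ts = SubjectTimeseries(data=data, grid=full_grid, tr_s=3.5)
        assert roi_snr(ts, roi, noise) == pytest.approx(100.0)

    def test_homogeneous_under_global_scaling(self, full_grid, rng):
        data = rng.standard_normal((full_grid.n_voxels, 40)) + 50
        roi = _roi_volume(full_grid, (slice(0, 3), slice(0, 3), slice(0, 2)))
        noise = _roi_volume(full_grid, (slice(6, 9), slice(6, 9), slice(2, 5)))
        ts = SubjectTimeseries(data=data, grid=full_grid, tr_s=3.5)
        ts2 = ts.copy_with(3.7 * data)
        assert roi_snr(ts2, roi, noise) == pytest.approx(
            roi_snr(ts, roi, noise))

    def test_matches_direct_recomputation(self, full_grid, rng):
        data = rng.standard_normal((full_grid.n_voxels, 30)) + 10
        roi = _roi_volume(full_grid, (slice(1, 4), slice(2, 5), slice(0, 3)))
        noise = _roi_volume(full_grid, (slice(6, 9), slice(6, 9), slice(2, 5)))
        ts = SubjectTimeseries(data=data, grid=full_grid, tr_s=3.5)
        got = roi_snr(ts, roi, noise)
        # spreadsheet-style recomputation from the raw arrays
        roi_vals = data[full_grid.extract(roi)]
        noise_avg = data[full_grid.extract(noise)].mean(axis=0)
        oracle = roi_vals.mean() / noise_avg.std(ddof=0)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_zero_noise_variance_rejected(self, full_grid):
        data = np.ones((full_grid.n_voxels, 10))
        roi = _roi_volume(full_grid, (0, 0, 0))
        noise = _roi_volume(full_grid, (5, 5, 2))
        ts = SubjectTimeseries(data=data, grid=full_grid, tr_s=3.5)
        with pytest.raises(ValueError, match="zero variance"):
            roi_snr(ts, roi, noise)


def _flood_fill_sizes(binary, connectivity):
    """Brute-force connected components by explicit flood fill."""
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and {6: abs(i) + abs(j) + abs(k) == 1,
             18: abs(i) + abs(j) + abs(k) <= 2,
             26: True}[connectivity]
    ]
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    dims = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < d for n, d in zip(nxt, dims)) \
                        and binary[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    stack.append(nxt)
        sizes.append(size)
    return sorted(sizes)


class TestClusterLabel:
    def test_empty_volume(self):
        labels, sizes = cluster_label(np.zeros((4, 4, 4), bool))
        assert sizes.size == 0

    def test_diagonal_adjacency_depends_on_connectivity(self):
        vol = np.zeros((4, 4, 4), bool)
        vol[1, 1, 1] = vol[2, 2, 2] = True  # 3-D diagonal neighbours
        assert cluster_label(vol, 6)[1].size == 2
        assert cluster_label(vol, 18)[1].size == 2
        assert cluster_label(vol, 26)[1].size == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        vol = rng.random((8, 8, 6)) < 0.35
        _, sizes = cluster_label(vol, connectivity)
        assert sorted(sizes.tolist()) == _flood_fill_sizes(vol, connectivity)
        assert sizes.sum() == vol.sum()  # sizes partition suprathreshold set


class TestMonteCarloThreshold:
    def test_deterministic_given_seed(self, full_grid):
        kw = dict(fwhm_mm=6.0, p_voxel=0.01, alpha=0.05, n_iter=120, seed=3)
        assert monte_carlo_cluster_threshold(full_grid, **kw) == \
            monte_carlo_cluster_threshold(full_grid, **kw)

    def test_unsmoothed_strict_threshold_small_clusters(self, full_grid):
        # independent voxels at p=0.001 almost never form clusters
        k = monte_carlo_cluster_threshold(full_grid, fwhm_mm=0.0,
                                          p_voxel=0.001, alpha=0.05,
                                          n_iter=300, seed=1)
        assert k <= 2

    def test_degenerate_p_warns_alpha_unreachable(self, full_grid):
        with pytest.warns(UserWarning, match="alpha.*unreachable"):
            k = monte_carlo_cluster_threshold(full_grid, fwhm_mm=0.0,
                                              p_voxel=0.999999, alpha=0.05,
                                              n_iter=100, seed=1)
        assert k > full_grid.n_voxels

    def test_monotone_in_smoothness_and_voxel_p(self, full_grid):
        ks = [
            monte_carlo_cluster_threshold(full_grid, fwhm_mm=f, p_voxel=0.01,
                                          alpha=0.05, n_iter=200, seed=2)
            for f in (0.0, 6.0, 12.0)
        ]
        assert ks[0] <= ks[1] <= ks[2]
        kp = [
            monte_carlo_cluster_threshold(full_grid, fwhm_mm=6.0, p_voxel=p,
                                          alpha=0.05, n_iter=200, seed=2)
            for p in (0.001, 0.01, 0.05)
        ]
        assert kp[0] <= kp[1] <= kp[2]


class TestRmAnova:
    def test_matches_pingouin_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        n, a, b = 12, 4, 2
        cube = rng.standard_normal((n, a, b)) + \
            np.arange(a)[None, :, None] * 0.5
        table = rm_anova_two_way(cube)
        records = [
            {"subject": s, "roi": f"r{i}", "dataset": f"d{j}",
             "y": cube[s, i, j]}
            for s in range(n) for i in range(a) for j in range(b)
        ]
        df = pd.DataFrame.from_records(records)
        oracle = pg.rm_anova(data=df, dv="y", within=["roi", "dataset"],
                             subject="subject", detailed=True)
        for effect, pg_name in [("roi", "roi"), ("dataset", "dataset"),
                                ("roi x dataset", "roi * dataset")]:
            mine = table.loc[table.effect == effect, "F"].item()
            theirs = oracle.loc[oracle.Source == pg_name, "F"].item()
            assert mine == pytest.approx(theirs, abs=1e-8)

    def test_cell_means_hand_computation(self, rng):
        # 2x2x2 table: sums of squares from explicit cell means
        y = rng.standard_normal((2, 2, 2))
        table = rm_anova_two_way(y)
        m = y.mean()
        ss_a = 2 * 2 * np.sum((y.mean(axis=(0, 2)) - m) ** 2)
        assert table.loc[table.effect == "roi", "ss"].item() == \
            pytest.approx(ss_a, abs=1e-8)


def _subject_table(rng, factor=1.0):
    rows = []
    for s in range(6):
        for roi in ("A", "B"):
            base_extent = 10 + s + (roi == "B") * 3
            base_peak = 4.0 + 0.1 * s
            base_snr = 50.0 + s
            for arm in ("original", "gcca"):
                f = factor if arm == "gcca" else 1.0
                rows.append({
                    "subject": f"s{s}", "roi": roi, "arm": arm,
                    "extent": base_extent * f, "peak_t": base_peak * f,
                    "snr": base_snr * f,
                })
    return pd.DataFrame(rows)


class TestCompareArms:
    def test_identical_arms_all_zero(self, rng):
        report = compare_arms(_subject_table(rng, factor=1.0))
        for metric in ("extent", "peak_t", "snr"):
            assert report.per_roi[f"pct_change_{metric}_mean"].eq(0).all()
            anova = report.anova[metric]
            assert anova.loc[anova.effect == "dataset", "F"].item() == 0.0

    def test_uniform_scaling_gives_fifty_percent(self, rng):
        report = compare_arms(_subject_table(rng, factor=1.5))
        for metric in ("extent", "peak_t", "snr"):
            np.testing.assert_allclose(
                report.per_roi[f"pct_change_{metric}_mean"], 50.0, atol=1e-10
            )
            anova = report.anova[metric]
            f_data = anova.loc[anova.effect == "dataset", "F"].item()
            assert f_data > 0

    def test_incomplete_table_rejected(self, rng):
        table = _subject_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            compare_arms(table)

    def test_missing_arm_rejected(self, rng):
        table = _subject_table(rng)
        table.loc[table.arm == "gcca", "arm"] = "denoised"
        with pytest.raises(ValueError, match="expected arms"):
            compare_arms(table)
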