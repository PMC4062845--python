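import numpy as np
import pytest
from scipy import stats

from ctradial.segmentation import NucleusMask
from ctradial.spatial3d import (
    CentroidRecord,
    center_distance,
    distance_frequency,
    geometric_center,
    pairwise_ct_distances,
    radial_fraction,
    region_volume,
)


def voxel_mask(shape, fill_idx, pixel_size=0.1, z_step=0.3):
    arr = np.zeros(shape, bool)
    for idx in fill_idx:
        arr[idx] = True
    return NucleusMask(arr, pixel_size=pixel_size, z_step=z_step)


def ball_mask(radius_um, voxel=(0.1, 0.1, 0.1)):
    vz, vy, vx = voxel[2], voxel[1], voxel[0]
    nz = int(2 * radius_um / vz) + 5
    ny = int(2 * radius_um / vy) + 5
    nx = int(2 * radius_um / vx) + 5
    z = (np.arange(nz) + 0.5 - nz / 2) * vz
    y = (np.arange(ny) + 0.5 - ny / 2) * vy
    x = (np.arange(nx) + 0.5 - nx / 2) * vx
    r2 = z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    return NucleusMask(r2 <= radius_um**2, pixel_size=vx, z_step=vz)


class TestGeometricCenter:
    def test_single_voxel_center_convention(self):
        m = voxel_mask((2, 2, 2), [(0, 0, 0)])
        rec = geometric_center(m)
        assert rec.center == pytest.approx((0.05, 0.05, 0.15))

    def test_symmetric_two_voxel_midpoint(self):
        m = voxel_mask((2, 3, 3), [(0, 1, 0), (0, 1, 2)])
        rec = geometric_center(m)
        assert rec.center == pytest.approx((0.15, 0.15, 0.15))

    def test_voxelized_ball_center(self):
        m = ball_mask(2.0)
        rec = geometric_center(m)
        # ball constructed symmetric about the grid centre
        nz, ny, nx = m.mask.shape
        expected = (nx / 2 * 0.1, ny / 2 * 0.1, nz / 2 * 0.1)
        assert np.allclose(rec.center, expected, atol=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            geometric_center(voxel_mask((2, 2, 2), []))


class TestCenterDistance:
    def rec(self, xyz):
        return CentroidRecord(1, "x", tuple(xyz), (0.1, 0.1, 0.3))

    def test_identical_centers(self):
        assert center_distance(self.rec([1, 2, 3]), self.rec([1, 2, 3])) == 0.0

    def test_3_4_5(self):
        assert center_distance(self.rec([0, 0, 0]), self.rec([3, 4, 0])) == pytest.approx(5.0)

    def test_mismatched_frames_rejected(self):
        a = self.rec([0, 0, 0])
        b = CentroidRecord(1, "y", (1.0, 1.0), (0.1, 0.1))
        with pytest.raises(ValueError):
            center_distance(a, b)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a, b, c = (self.rec(rng.uniform(0, 10, 3)) for _ in range(3))
            ab, ba = center_distance(a, b), center_distance(b, a)
            assert ab == ba >= 0
            assert ab <= center_distance(a, c) + center_distance(c, b) + 1e-12


class TestDistanceFrequency:
    def test_counting(self):
        df = distance_frequency([0.5, 1.5, 1.6], bin_width=1.0)
        assert df["count"].tolist() == [1, 2]

    def test_relative_frequencies_sum_to_one(self):
        rng = np.random.default_rng(3)
        df = distance_frequency(rng.uniform(0, 7, 200), bin_width=0.5)
        assert df["rel_freq"].sum() == pytest.approx(1.0)

    def test_uniform_ball_matches_radial_density(self):
        """Uniform points in a ball of radius R have radial density 3r^2/R^3."""
        rng = np.random.default_rng(4)
        R, n = 5.0, 1000
        r = R * rng.uniform(0, 1, n) ** (1 / 3)
        df = distance_frequency(r, bin_width=1.0)
        for _, row in df.iterrows():
            p = (row.bin_right**3 - row.bin_left**3) / R**3
            se = np.sqrt(p * (1 - p) / n)
            assert abs(row.rel_freq - p) < 4 * se + 1e-9

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            distance_frequency([], 1.0)
        with pytest.raises(ValueError):
            distance_frequency([1.0], 0.0)


class TestPairwiseCTDistances:
    def rec(self, xyz, nid=0):
        return CentroidRecord(nid, "x", tuple(map(float, xyz)), (0.1, 0.1, 0.3))

    def test_single_pair(self):
        ds = pairwise_ct_distances([([self.rec([0, 0, 0])], [self.rec([6, 0, 0])])])
        assert ds.distances == (6.0,)
        assert all(v == 6.0 for k, v in ds.summary.items())

    def test_homolog_median(self):
        ds = pairwise_ct_distances(
            [([self.rec([0, 0, 0])], [self.rec([3, 0, 0]), self.rec([0, 4, 0])])]
        )
        assert sorted(ds.distances) == [3.0, 4.0]
        assert ds.summary["median"] == pytest.approx(3.5)

    def test_nuclei_missing_group_skipped(self):
        ds = pairwise_ct_distances(
            [
                ([self.rec([0, 0, 0])], []),
                ([self.rec([0, 0, 0])], [self.rec([1, 0, 0])]),
            ]
        )
        assert ds.n_nuclei == 1
        with pytest.raises(ValueError):
            pairwise_ct_distances([([], [])])

    def test_summary_recomputable_from_distances(self):
        rng = np.random.default_rng(5)
        pairs = [
            ([self.rec(rng.uniform(0, 5, 3))], [self.rec(rng.uniform(0, 5, 3))])
            for _ in range(30)
        ]
        ds = pairwise_ct_distances(pairs)
        d = np.array(ds.distances)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        assert ds.summary == {
            "min": d.min(),
            "q1": q1,
            "median": med,
            "q3": q3,
            "max": d.max(),
        }


class TestRegionVolume:
    def test_voxel_count_times_voxel_volume(self):
        m = voxel_mask((10, 10, 10), [(i, j, k) for i in range(10) for j in range(10) for k in range(1)])
        # 100 voxels of 0.1 x 0.1 x 0.3
        assert region_volume(m) == pytest.approx(100 * 0.1 * 0.1 * 0.3)

    def test_voxelized_ball_volume(self):
        m = ball_mask(2.0)
        assert region_volume(m) == pytest.approx(4 / 3 * np.pi * 8, rel=0.05)

    def test_equal_volume_conditions_not_significant(self):
        rng = np.random.default_rng(11)
        a = [region_volume(ball_mask(2.0 + rng.normal(0, 0.05))) for _ in range(12)]
        b = [region_volume(ball_mask(2.0 + rng.normal(0, 0.05))) for _ in range(12)]
        assert stats.ttest_ind(a, b, equal_var=False).pvalue > 0.05

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            region_volume(voxel_mask((2, 2, 2), []))


class TestControlRecoveredIndistinguishable:
    """Territory-to-centre distance distributions from two populations drawn
    from the same placement distribution should not differ statistically."""

    REPLICATES = 30
    N_NUCLEI = 25

    @staticmethod
    def _radial_distances(seed):
        from ctradial.segmentation import qc_filter, segment_ct, segment_nucleus_3d
        from ctradial.synthetic import CTSpec, simulate_population

        pop = simulate_population(
            TestControlRecoveredIndistinguishable.N_NUCLEI,
            cts=[CTSpec(rho="interior")],
            seed=seed,
            dims=3,
        )
        out = []
        for _, dapi, probes in pop.scenes:
            for mask in qc_filter(segment_nucleus_3d(dapi)):
                nuc = geometric_center(mask)
                for region in segment_ct(probes["A"], mask):
                    out.append(center_distance(nuc, geometric_center(region)))
        return out

    def test_same_distribution_rarely_flagged(self):
        ok = 0
        for rep in range(self.REPLICATES):
            a = self._radial_distances(seed=6000 + 2 * rep)
            b = self._radial_distances(seed=6001 + 2 * rep)
            ok += stats.ttest_ind(a, b, equal_var=False).pvalue > 0.05
        assert ok >= 0.9 * self.REPLICATES, ok


class TestRadialFraction:
    def test_center_is_zero_boundary_near_one(self):
        m = ball_mask(2.0)
        c = geometric_center(m).center
        assert radial_fraction(m, c) == pytest.approx(0.0, abs=0.05)
        near_edge = (c[0] + 1.9, c[1], c[2])
        assert radial_fraction(m, near_edge) == pytest.approx(0.95, abs=0.05)
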