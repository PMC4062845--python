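import numpy as np
import pytest
from scipy import ndimage

from ctradial.exceptions import DegenerateMaskError, DegenerateShellError, EmptySignalError
from ctradial.geometry import ShellScheme, disk_shell_radii
from ctradial.segmentation import ChannelImage, qc_filter, segment_nucleus_2d
from ctradial.shells import (
    background_correct,
    normalized_ratio,
    partition_mask,
    quantify_shells,
)
from ctradial.synthetic import CTTruth, default_scene_2d, simulate_nucleus_2d, simulate_population

from conftest import make_disk_mask, make_ellipse_mask


def shell_max_radii(partition, mask):
    """Maximum centre-distance per shell (pixel units), innermost first."""
    c = np.array(mask.mask.shape) // 2
    out = []
    for shell in range(1, partition.k + 1):
        idx = np.argwhere(partition.shell_labels == shell)
        out.append(np.sqrt(((idx - c) ** 2).sum(axis=1)).max())
    return out


class TestPartitionMask:
    def test_disk_equal_area_boundary_radii_match_oracle(self):
        mask = make_disk_mask(100)
        part = partition_mask(mask, ShellScheme.equal_area(5))
        oracle = disk_shell_radii(100, ShellScheme.equal_area(5).area_fractions)
        assert np.allclose(shell_max_radii(part, mask), oracle, atol=1.0)

    def test_disk_equal_volume_innermost_fraction(self):
        mask = make_disk_mask(100)
        part = partition_mask(mask, ShellScheme.equal_volume(5))
        assert part.achieved_fractions[0] == pytest.approx(0.3420, abs=0.005)

    def test_single_shell_labels_everything(self):
        mask = make_disk_mask(20)
        part = partition_mask(mask, ShellScheme.equal_area(1))
        assert np.array_equal(part.shell_labels == 1, mask.mask)

    def test_full_coverage_and_exclusive_labels(self):
        mask = make_ellipse_mask(30, 20)
        part = partition_mask(mask, ShellScheme.equal_volume(5))
        labels = part.shell_labels
        assert np.all((labels > 0) == mask.mask)
        assert labels.max() == 5
        counts = np.bincount(labels.ravel())[1:]
        assert np.allclose(counts / mask.size_px, part.achieved_fractions)

    def test_mask_smaller_than_k_raises(self):
        tiny = make_disk_mask(1)
        tiny.mask[:] = False
        tiny.mask[3, 3] = True
        with pytest.raises(DegenerateMaskError):
            partition_mask(tiny, ShellScheme.equal_area(5))

    def test_achieved_fractions_converge_with_mask_size(self):
        scheme = ShellScheme.equal_volume(5)
        errs = []
        for r in (25, 50, 100, 200):
            part = partition_mask(make_disk_mask(r), scheme)
            errs.append(
                np.abs(np.array(part.achieved_fractions) - scheme.area_fractions).max()
            )
        assert all(a >= b for a, b in zip(errs, errs[1:]))

    def test_shape_respecting_on_ellipse(self):
        mask = make_ellipse_mask(40, 25)
        part = partition_mask(mask, ShellScheme.equal_area(5))
        dist = ndimage.distance_transform_edt(mask.mask)
        deepest = np.unravel_index(np.argmax(dist), dist.shape)
        assert part.shell_labels[deepest] == 1
        boundary = mask.mask & ~ndimage.binary_erosion(mask.mask)
        assert np.all(part.shell_labels[boundary] == 5)

    def test_nested_by_depth(self):
        mask = make_ellipse_mask(30, 18)
        part = partition_mask(mask, ShellScheme.equal_area(4))
        dist = ndimage.distance_transform_edt(mask.mask)
        for i in range(1, 4):
            inner_min = dist[part.shell_labels == i].min()
            outer_max = dist[part.shell_labels == i + 1].max()
            assert inner_min >= outer_max - 1e-9

    def test_deterministic(self):
        mask = make_ellipse_mask(25, 15)
        p1 = partition_mask(mask, ShellScheme.equal_area(5))
        p2 = partition_mask(mask, ShellScheme.equal_area(5))
        assert np.array_equal(p1.shell_labels, p2.shell_labels)

    def test_erosion_method_same_fractions(self):
        mask = make_disk_mask(60)
        part = partition_mask(mask, ShellScheme.equal_area(5), method="erosion")
        assert np.allclose(part.achieved_fractions, 0.2, atol=1e-3)


class TestBackgroundCorrect:
    def test_constant_image_subtract(self, flat_image):
        mask = make_disk_mask(20)
        out = background_correct(flat_image(mask, 10.0), mask, "subtract_mean")
        assert np.all(out.data[mask.mask] == 0)
        assert np.all(out.data[~mask.mask] == 10.0)  # outside untouched

    def test_constant_image_divide(self, flat_image):
        mask = make_disk_mask(20)
        out = background_correct(flat_image(mask, 10.0), mask, "divide_mean")
        assert np.all(out.data[mask.mask] == 1.0)

    def test_threshold_mean_rule(self):
        mask_arr = np.zeros((2, 2), bool)
        mask_arr[:] = True
        from ctradial.segmentation import NucleusMask

        mask = NucleusMask(mask_arr)
        img = ChannelImage(np.array([[10.0, 20.0], [30.0, 40.0]]))
        out = background_correct(img, mask, "threshold_mean")
        assert out.data.tolist() == [[0.0, 0.0], [30.0, 40.0]]

    def test_none_mode_is_identity(self, flat_image):
        mask = make_disk_mask(10)
        img = flat_image(mask, 7.0)
        assert background_correct(img, mask, "none") is img

    def test_empty_mask_raises(self, flat_image):
        mask = make_disk_mask(10)
        mask.mask[:] = False
        with pytest.raises(DegenerateMaskError):
            background_correct(flat_image(mask, 1.0), mask, "subtract_mean")


class TestNormalizedRatio:
    def test_probe_all_in_innermost(self):
        n = normalized_ratio([100, 0, 0, 0, 0], [20, 20, 20, 20, 20])
        assert n.tolist() == pytest.approx([5, 0, 0, 0, 0])

    def test_printed_formula_substitution(self):
        n = normalized_ratio([10, 10, 20, 30, 30], [34, 20, 17, 16, 13])
        assert n == pytest.approx([0.294, 0.5, 1.176, 1.875, 2.308], abs=1e-3)

    def test_zero_dapi_with_probe_raises(self):
        with pytest.raises(DegenerateShellError):
            normalized_ratio([50, 50, 0, 0, 0], [0, 50, 25, 25, 0])

    def test_zero_dapi_zero_probe_gives_zero(self):
        n = normalized_ratio([50, 50, 0, 0, 0], [25, 50, 15, 10, 0])
        assert n[-1] == 0.0


class TestQuantifyShells:
    def _disk_setup(self, k=5):
        mask = make_disk_mask(50)
        part = partition_mask(mask, ShellScheme.equal_area(k))
        return mask, part

    def test_probe_proportional_to_dapi_gives_unity(self, flat_image):
        mask, part = self._disk_setup()
        dapi = flat_image(mask, 10.0)
        probe = ChannelImage(3.0 * dapi.data, role="probe_A")
        sig = quantify_shells(part, probe, dapi, background_mode="none")
        assert np.allclose(sig.n, 1.0, atol=1e-9)

    def test_conservation_on_simulated_population(self):
        pop = simulate_population(20, cts=None, seed=9)
        scheme = ShellScheme.equal_area(5)
        checked = 0
        for _, dapi, probes in pop.scenes:
            masks = qc_filter(segment_nucleus_2d(dapi))
            for mask in masks:
                part = partition_mask(mask, scheme)
                sig = quantify_shells(part, probes["A"], dapi)
                assert sum(d * n for d, n in zip(sig.d, sig.n)) == pytest.approx(100.0)
                assert sum(sig.p) == pytest.approx(100.0, abs=1e-6)
                assert sum(sig.d) == pytest.approx(100.0, abs=1e-6)
                checked += 1
        assert checked >= 18

    def test_empty_probe_raises(self, flat_image):
        mask, part = self._disk_setup()
        dapi = flat_image(mask, 10.0)
        probe = ChannelImage(np.zeros_like(dapi.data), role="probe_A")
        with pytest.raises(EmptySignalError):
            quantify_shells(part, probe, dapi, background_mode="none")

    def test_binary_mode_equal_area_dapi_fractions(self, flat_image):
        mask, part = self._disk_setup()
        dapi = flat_image(mask, 10.0)
        probe = flat_image(mask, 4.0, role="probe_A")
        sig = quantify_shells(part, probe, dapi, background_mode="none", quantification="binary")
        assert np.allclose(sig.d, 20.0, atol=0.1)


class TestRotationEquivariance:
    @staticmethod
    def _pipeline_n(dapi, probe):
        (mask,) = qc_filter(segment_nucleus_2d(dapi))
        part = partition_mask(mask, ShellScheme.equal_area(5))
        return np.asarray(quantify_shells(part, probe, dapi).n)

    @staticmethod
    def _rot(img, rot):
        return ChannelImage(
            np.rot90(img.data, rot).copy(), role=img.role, pixel_size=img.pixel_size
        )

    @pytest.mark.parametrize("rot", [1, 2, 3])
    def test_symmetric_disk_fixture_exact(self, rot):
        truth = default_scene_2d(
            seed=7,
            shape=(81, 81),
            center_px=(40.5, 40.5),
            semi_axes_um=(6.0, 6.0),
            orientation=0.0,
            poisson_scale=0.0,
            gaussian_sd=0.0,
            texture_amp=0.0,
            cts=(CTTruth("A", rho=0.0, theta=0.0),),
        )
        dapi, probes = simulate_nucleus_2d(truth)
        n0 = self._pipeline_n(dapi, probes["A"])
        n1 = self._pipeline_n(self._rot(dapi, rot), self._rot(probes["A"], rot))
        assert np.abs(n1 - n0).max() <= 1e-6

    def test_off_center_blob_pixel_level_bound(self):
        # exact-count shell cuts reassign a handful of equidistant pixels
        # under rotation; the effect is bounded at the single-pixel level
        truth = default_scene_2d(
            seed=7,
            poisson_scale=0.0,
            gaussian_sd=0.0,
            texture_amp=0.0,
            cts=(CTTruth("A", rho=0.55, theta=0.8),),
        )
        dapi, probes = simulate_nucleus_2d(truth)
        n0 = self._pipeline_n(dapi, probes["A"])
        n1 = self._pipeline_n(self._rot(dapi, 1), self._rot(probes["A"], 1))
        assert np.abs(n1 - n0).max() < 0.1
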