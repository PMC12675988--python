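import numpy as np
import pytest

from rhizoct.gradients import (
    default_bin_edges,
    distance_from_mask,
    distance_from_root,
    grey_profile,
    shell_profile,
)
from rhizoct.validation import brute_force_edt
from rhizoct.volume_io import LabelVolume, SoilClass, Volume3D


class TestDistanceFromRoot:
    def test_three_four_five_triangle(self):
        m = np.zeros((21, 21, 21), bool)
        m[10, 10, 10] = True
        d = distance_from_mask(m, 1.0)
        assert d.dist_mm[13, 14, 10] == pytest.approx(5.0)
        assert d.dist_mm[10, 10, 10] == 0.0

    def test_plane_gives_orthogonal_distance(self):
        m = np.zeros((9, 5, 5), bool)
        m[4] = True
        d = distance_from_mask(m, 0.0182)
        for k in range(9):
            assert d.dist_mm[k, 2, 2] == pytest.approx(abs(k - 4) * 0.0182)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((32, 32, 32)) < 0.01
        if not m.any():
            m[0, 0, 0] = True
        d = distance_from_mask(m, 0.0182)
        oracle = brute_force_edt(m, 0.0182)
        assert np.abs(d.dist_mm - oracle).max() < 1e-9

    def test_no_new_roots_rejected(self):
        labels = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError, match="no ROOT_NEW"):
            distance_from_root(labels)

    def test_zero_exactly_on_new_roots(self, small_core):
        la = small_core["labels_after"]
        d = distance_from_root(la)
        root = la.mask(SoilClass.ROOT_NEW)
        assert np.all((d.dist_mm == 0) == root)


def _center_root_distance(shape=(40, 80, 80), voxel_mm=0.0182):
    m = np.zeros(shape, bool)
    cy, cx = shape[1] // 2, shape[2] // 2
    m[:, cy - 1: cy + 2, cx - 1: cx + 2] = True
    return m, distance_from_mask(m, voxel_mm)


class TestShellProfile:
    def test_target_equals_domain_gives_ones(self):
        root, dist = _center_root_distance()
        domain = ~root
        prof = shell_profile(dist, domain, domain)
        assert np.allclose(prof.local_value[~prof.empty_bins], 1.0)

    def test_uniform_random_target_within_binomial_error(self):
        root, dist = _center_root_distance()
        rng = np.random.default_rng(4)
        p = 0.3
        target = rng.random(root.shape) < p
        prof = shell_profile(dist, target, ~root)
        for value, n in zip(prof.local_value, prof.n_domain_voxels):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(value - p) < 5 * se

    def test_shells_partition_domain(self):
        root, dist = _center_root_distance()
        domain = ~root
        prof = shell_profile(dist, np.zeros_like(root), domain)
        border = dist.voxel_mm
        in_range = domain & (dist.dist_mm > border) & (dist.dist_mm <= 1.0)
        assert prof.n_domain_voxels.sum() == in_range.sum()

    def test_volume_weighted_mean_equals_aggregate_fraction(self):
        root, dist = _center_root_distance()
        rng = np.random.default_rng(5)
        target = rng.random(root.shape) < 0.2
        domain = ~root
        prof = shell_profile(dist, target, domain)
        agg = prof.n_target_voxels.sum() / prof.n_domain_voxels.sum()
        weighted = np.sum(prof.local_value * prof.n_domain_voxels) / prof.n_domain_voxels.sum()
        assert weighted == pytest.approx(agg, abs=1e-15)

    def test_translation_invariance(self):
        # 0.1 mm voxels keep the whole 1 mm band inside the grid before and
        # after the shift, so no shell is clipped by a volume border
        rng = np.random.default_rng(6)
        root = np.zeros((40, 44, 44), bool)
        root[14:26, 20:24, 20:24] = True
        target = rng.random(root.shape) < 0.25
        p1 = shell_profile(distance_from_mask(root, 0.1), target, ~root)
        shift = (3, 5, -4)
        p2 = shell_profile(
            distance_from_mask(np.roll(root, shift, (0, 1, 2)), 0.1),
            np.roll(target, shift, (0, 1, 2)), ~np.roll(root, shift, (0, 1, 2)))
        np.testing.assert_allclose(p1.local_value, p2.local_value)

    def test_empty_bins_flagged_not_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[3, 3, 3] = True
        dist = distance_from_mask(m, 1.0)  # 1 mm voxels: nothing beyond ~5 mm
        prof = shell_profile(dist, ~m, ~m, bin_edges_mm=[6.0, 7.0, 8.0])
        assert prof.empty_bins.all()
        assert np.isnan(prof.local_value).all()

    def test_unordered_bins_rejected(self):
        root, dist = _center_root_distance((10, 20, 20))
        with pytest.raises(ValueError):
            shell_profile(dist, ~root, ~root, bin_edges_mm=[0.4, 0.2])

    def test_border_exclusion_removes_surface_layer(self):
        root, dist = _center_root_distance()
        domain = ~root
        edges = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        excl = shell_profile(dist, domain, domain, bin_edges_mm=edges)
        surface = domain & (dist.dist_mm > 0) & (dist.dist_mm <= dist.voxel_mm)
        assert surface.sum() > 0  # the root-adjacent layer exists...
        full = shell_profile(dist, domain, domain, bin_edges_mm=edges,
                             border_exclusion_mm=0.0)
        # ...is excluded by the default one-voxel border, and re-enters at 0
        assert full.n_domain_voxels[0] == excl.n_domain_voxels[0] + surface.sum()


class TestDefaultBins:
    def test_default_edges_cover_one_mm_in_0p2_steps(self):
        edges = default_bin_edges(0.0182)
        assert edges[0] == pytest.approx(0.0182)
        np.testing.assert_allclose(edges[1:], [0.2, 0.4, 0.6, 0.8, 1.0])

    def test_finer_0p1_variant_supported(self):
        edges = default_bin_edges(0.0182, step_mm=0.1)
        assert len(edges) == 11

    def test_each_0p2_increment_spans_about_ten_voxel_layers(self):
        assert int(0.2 / 0.0182) == 10


class TestGreyProfile:
    def test_constant_grey_gives_constant_means(self):
        root, dist = _center_root_distance()
        grey = Volume3D(np.full(root.shape, 777, dtype=np.uint16), 0.0182)
        prof = grey_profile(dist, grey, ~root)
        assert np.allclose(prof.local_value, 777.0)
        assert np.allclose(prof.cumulative_value, 777.0)

    def test_grey_equal_to_distance_is_monotone(self):
        root, dist = _center_root_distance()
        grey = Volume3D(dist.dist_mm * 1000, 0.0182)
        prof = grey_profile(dist, grey, ~root)
        assert np.all(np.diff(prof.local_value) > 0)
        # cumulative mean lags the per-bin mean for an increasing signal
        assert np.all(prof.cumulative_value[1:] < prof.local_value[1:])

    def test_compacted_rhizosphere_denser_near_root(self, small_core):
        # generator compacts macropores near the root: solid fraction and hence
        # mean grey value rise towards the root surface
        la, ga = small_core["labels_after"], small_core["grey_after"]
        lb = small_core["labels_before"]
        dist = distance_from_root(la)
        domain = lb.soil_domain_mask() & la.soil_domain_mask()
        prof = grey_profile(dist, ga, domain)
        assert prof.local_value[1] > prof.local_value[-1]
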