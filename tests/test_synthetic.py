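import numpy as np
import pytest
from scipy import ndimage, stats

from conftest import small_params
from rhizoct.pore_metrics import total_macroporosity
from rhizoct.root_masks import ClassShares
from rhizoct.synthetic import (
    GroundTruth,
    InfeasibleParamsError,
    SyntheticParams,
    generate_before,
    grow_root,
    simulate_core,
    synthesize_rhizosheath_table,
    vary,
)
from rhizoct.volume_io import SoilClass


class TestGenerateBefore:
    def test_zero_target_gives_pore_free_core(self):
        params = small_params(macroporosity_target=0.0, n_biopores=0)
        _, labels = generate_before(params)
        assert not labels.pore_mask().any()

    def test_biopores_with_zero_target_is_infeasible(self):
        with pytest.raises(InfeasibleParamsError):
            generate_before(small_params(macroporosity_target=0.0, n_biopores=1))

    def test_oversized_biopore_is_infeasible(self):
        with pytest.raises(InfeasibleParamsError, match="fit"):
            generate_before(small_params(shape=(16, 16, 16),
                                         biopore_diameter_mm=0.4, n_biopores=1))

    def test_requested_biopore_count_realized_as_components(self):
        params = SyntheticParams(shape=(64, 64, 64), n_biopores=3,
                                 biopore_diameter_mm=0.4,
                                 macroporosity_target=0.30, seed=2)
        _, labels = generate_before(params)
        n = ndimage.label(labels.mask(SoilClass.BIOPORE), np.ones((3, 3, 3)))[1]
        assert n == 3

    def test_macroporosity_within_ten_percent_relative(self):
        for seed in (0, 1):
            params = small_params(seed=seed, macroporosity_target=0.15)
            _, labels = generate_before(params)
            phi = total_macroporosity(labels.pore_mask(), labels.soil_domain_mask())
            assert abs(phi - 0.15) <= 0.015

    def test_same_seed_identical_volumes(self):
        params = small_params(seed=42)
        g1, l1 = generate_before(params)
        g2, l2 = generate_before(params)
        np.testing.assert_array_equal(g1.data, g2.data)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_grey_values_separate_solid_and_pore(self):
        grey, labels = generate_before(small_params(seed=1))
        pore = labels.pore_mask()
        assert grey.data[~pore].mean() > grey.data[pore].mean() + 10000


class TestGrowRoot:
    def test_deterministic_under_fixed_seed(self):
        params = small_params(seed=8)
        _, labels = generate_before(params)
        a1 = grow_root(labels, params)
        a2 = grow_root(labels, params)
        np.testing.assert_array_equal(a1[0].labels, a2[0].labels)
        np.testing.assert_array_equal(a1[1].data, a2[1].data)

    def test_before_volume_not_mutated(self):
        params = small_params(seed=9)
        _, labels = generate_before(params)
        snapshot = labels.labels.copy()
        grow_root(labels, params)
        np.testing.assert_array_equal(labels.labels, snapshot)

    def test_root_is_single_connected_tube(self, small_core):
        root = small_core["labels_after"].mask(SoilClass.ROOT_NEW)
        n = ndimage.label(root, np.ones((3, 3, 3)))[1]
        assert n == 1

    def test_ledger_equals_label_diff_exactly(self, small_core):
        lb = small_core["labels_before"].labels
        la = small_core["labels_after"].labels
        truth = small_core["truth"]
        diff = np.argwhere(lb != la)
        assert set(map(tuple, diff)) == set(map(tuple, truth.change_coords))
        changes = truth.per_voxel_changes()
        for (z, y, x), (b, a) in list(changes.items())[::97]:
            assert lb[z, y, x] == b and la[z, y, x] == a

    def test_shares_sum_to_100(self, small_core):
        s = small_core["truth"].imposed_class_shares
        assert sum(s.as_tuple()) == pytest.approx(100.0, abs=1e-9)

    def test_forced_biopore_preference(self):
        params = small_params(p_macropore_preference=1.0, seed=10)
        sim = simulate_core(params)
        s = sim["truth"].imposed_class_shares
        assert s.biopore_pct >= 95.0
        assert s.matrix_pct <= 5.0

    def test_no_perturbation_changes_only_root_voxels(self):
        params = small_params(compaction_amplitude=0.0,
                              wall_effect_amplitude=0.0, seed=12)
        sim = simulate_core(params)
        truth = sim["truth"]
        assert np.all(truth.class_after == int(SoilClass.ROOT_NEW))

    def test_compaction_ledger_confined_to_band(self):
        params = small_params(compaction_amplitude=-0.5,
                              compaction_band_mm=(0.2, 0.4),
                              wall_effect_amplitude=0.0, seed=13)
        sim = simulate_core(params)
        truth = sim["truth"]
        la = sim["labels_after"]
        dist = ndimage.distance_transform_edt(
            ~la.mask(SoilClass.ROOT_NEW)) * params.voxel_mm
        compacted = truth.class_after == int(SoilClass.MATRIX)
        d = dist[tuple(truth.change_coords[compacted].T)]
        assert d.min() > 0.2 and d.max() <= 0.4 + 1e-12
        # the imposed induced profile is negative exactly in the 0.2-0.4 bin
        prof = truth.imposed_induced_profile
        assert prof[1] < 0 and np.allclose(prof[[0, 2, 3, 4]], 0.0, atol=1e-12)

    def test_grid_too_small_for_analysis_band(self):
        params = small_params(shape=(24, 64, 64))
        _, labels = generate_before(params)
        with pytest.raises(InfeasibleParamsError, match="band"):
            grow_root(labels, params)


class TestRhizosheathTable:
    @staticmethod
    def _truths(shares_pct):
        out = []
        for i, s in enumerate(shares_pct):
            out.append(GroundTruth(
                core_id=f"c{i}", root_path=np.zeros((1, 3), int),
                change_coords=np.zeros((0, 3), int),
                class_before=np.zeros(0, int), class_after=np.zeros(0, int),
                imposed_class_shares=ClassShares(100.0 - s, s / 2, s / 2),
                imposed_induced_bin_edges_mm=np.array([0.0, 1.0]),
                imposed_induced_profile=np.zeros(1)))
        return out

    def test_noise_free_table_is_perfectly_monotone(self):
        from rhizoct.reporting import spearman_assoc

        t = synthesize_rhizosheath_table(self._truths([10, 35, 50, 75, 90]),
                                         noise_sd=0.0)
        rho1, _ = spearman_assoc(t.rhizosheath_mass_g, t.macropore_share_pct)
        rho2, _ = spearman_assoc(t.rhizosheath_mass_g, t.tracer_activity_kBq)
        assert rho1 == 1.0 and rho2 == 1.0

    def test_generating_equations_recorded(self):
        t = synthesize_rhizosheath_table(self._truths([20, 60]), noise_sd=0.0)
        assert "mass_g" in t.attrs["generating_equations"]
        assert t.attrs["coefficients"]["mass_slope"] > 0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synthesize_rhizosheath_table(self._truths([50]), noise_sd=-1.0)

    def test_slope_recovered_under_moderate_noise(self):
        # power calibration: n=24 cores, moderate noise, 200 replicates
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(200):
            shares = rng.uniform(5, 95, size=24)
            table = synthesize_rhizosheath_table(self._truths(shares),
                                                 noise_sd=0.3, seed=rep)
            res = stats.linregress(table.macropore_share_pct / 100,
                                   table.rhizosheath_mass_g)
            if res.slope > 0 and res.pvalue < 0.05:
                hits += 1
        assert hits >= 180


def test_vary_returns_modified_copy():
    p = small_params()
    q = vary(p, seed=99, p_macropore_preference=1.0)
    assert q.seed == 99 and p.seed != 99
    assert q.shape == p.shape
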