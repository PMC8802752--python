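"""Unit and oracle-equivalence tests for the five intrinsic-activity metrics."""

import numpy as np
import pytest

from restiba.core import BoldSeries, MetricMap, PipelineOrderError
from restiba.activity_metrics import (
    MetricConfig, compute_alff, compute_all_metrics, compute_dc, compute_falff,
    compute_peraf, compute_reho, gaussian_smooth, kendall_w, peraf_series,
    standardize_by_global_mean)
from conftest import make_series
from oracles import naive_alff, naive_dc, naive_falff, naive_kcc, naive_peraf, naive_reho

TR = 3.0


def unfiltered(data, **kw):
    s = make_series(data, tr=TR, **kw)
    return BoldSeries(s.data, s.tr_s, s.mask, volumes_discarded=True,
                      detrended=True, nuisance_regressed=True)


def filtered(data, **kw):
    s = unfiltered(data, **kw)
    return BoldSeries(s.data, s.tr_s, s.mask, volumes_discarded=True,
                      detrended=True, nuisance_regressed=True, filtered=True)


class TestOracleEquivalence:
    """All five metrics against naive per-voxel reference implementations."""

    def test_alff_matches_naive_dft(self, small_noise_volume):
        vol, mask = small_noise_volume
        ours = compute_alff(unfiltered(vol), 0.01, 0.08).data
        ref = naive_alff(vol, mask, TR, 0.01, 0.08)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_falff_matches_naive_dft(self, small_noise_volume):
        vol, mask = small_noise_volume
        ours = compute_falff(unfiltered(vol), 0.01, 0.08).data
        ref = naive_falff(vol, mask, TR, 0.01, 0.08)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_peraf_matches_naive(self, small_noise_volume):
        vol, mask = small_noise_volume
        shifted = vol + 100.0  # positive mean intensity
        ours = compute_peraf(make_series(shifted, tr=TR)).data
        ref = naive_peraf(shifted, mask)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_reho_matches_naive_kcc(self, small_noise_volume):
        vol, mask = small_noise_volume
        ours = compute_reho(filtered(vol), 27).data
        ref = naive_reho(vol, mask, 27)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    @pytest.mark.parametrize("k", [7, 19])
    def test_reho_other_neighbourhoods(self, small_noise_volume, k):
        vol, mask = small_noise_volume
        ours = compute_reho(filtered(vol), k).data
        ref = naive_reho(vol, mask, k)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_dc_matches_naive_pairwise(self, small_noise_volume):
        vol, mask = small_noise_volume
        ours = compute_dc(filtered(vol), 0.25, "binarized").data
        ref = naive_dc(vol, mask, 0.25)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_weighted_dc_matches_naive(self, small_noise_volume):
        vol, mask = small_noise_volume
        ours = compute_dc(filtered(vol), 0.25, "weighted").data
        ref = naive_dc(vol, mask, 0.25, weighted=True)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_dc_independent_of_block_size(self, small_noise_volume):
        vol, _ = small_noise_volume
        a = compute_dc(filtered(vol), 0.25, block_size=7).data
        b = compute_dc(filtered(vol), 0.25, block_size=100000).data
        np.testing.assert_array_equal(a, b)


class TestAmplitudeIdentities:
    def test_constant_series_zero_alff(self):
        out = compute_alff(unfiltered(np.full((1, 1, 1, 40), 9.0)))
        assert out.data[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_alff_homogeneous_of_degree_one(self, rng):
        vol = rng.normal(size=(2, 2, 2, 40))
        a1 = compute_alff(unfiltered(vol)).data
        a2 = compute_alff(unfiltered(2.0 * vol)).data
        np.testing.assert_allclose(a2, 2.0 * a1, atol=1e-10)

    def test_single_bin_sinusoid_amplitude(self):
        # 0.05 Hz is bin 12 of an 80-point grid at TR 3 s
        t = np.arange(80) * TR
        wave = 3.0 * np.sin(2 * np.pi * 0.05 * t)
        band_bins = np.sum((np.fft.rfftfreq(80, TR) >= 0.01)
                           & (np.fft.rfftfreq(80, TR) <= 0.08))
        out = compute_alff(unfiltered(wave))
        assert out.data[0, 0, 0] == pytest.approx(3.0 / band_bins, abs=1e-8)

    def test_falff_one_for_pure_in_band_signal(self):
        t = np.arange(100) * TR
        wave = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.03 * t)
        out = compute_falff(unfiltered(wave))
        assert out.data[0, 0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_falff_zero_for_out_of_band_signal(self):
        t = np.arange(100) * TR
        wave = np.sin(2 * np.pi * 0.12 * t)
        out = compute_falff(unfiltered(wave))
        assert out.data[0, 0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_falff_half_for_equal_in_and_out_of_band_pair(self):
        t = np.arange(100) * TR
        wave = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.12 * t)
        out = compute_falff(unfiltered(wave))
        assert out.data[0, 0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_filtered_input_rejected(self, rng):
        f = filtered(rng.normal(size=(1, 1, 1, 40)))
        with pytest.raises(PipelineOrderError):
            compute_alff(f)
        with pytest.raises(PipelineOrderError):
            compute_falff(f)


class TestPerAF:
    def test_printed_formula_hand_case(self):
        assert peraf_series(np.array([90.0, 110.0])) == pytest.approx(10.0)

    def test_constant_series_zero(self):
        assert peraf_series(np.full(10, 42.0)) == pytest.approx(0.0)

    def test_scale_invariant(self, rng):
        x = rng.normal(100.0, 5.0, size=50)
        assert peraf_series(3.0 * x) == pytest.approx(peraf_series(x))

    def test_nonpositive_mean_voxel_zeroed(self):
        vol = np.zeros((2, 1, 1, 4))
        vol[0, 0, 0] = [90, 110, 90, 110]
        vol[1, 0, 0] = [-1, 1, -1, 1]  # zero mean
        out = compute_peraf(make_series(vol, tr=TR))
        assert out.data[0, 0, 0] == pytest.approx(10.0)
        assert out.data[1, 0, 0] == 0.0

    def test_filtered_series_uses_restored_mean(self, rng):
        base = rng.normal(100.0, 2.0, size=(3, 3, 3, 40))
        from restiba.temporal_preprocess import (discard_initial_volumes,
                                                 ideal_bandpass, linear_detrend,
                                                 nuisance_regress, NuisanceSet)
        s = linear_detrend(discard_initial_volumes(make_series(base, tr=TR), 0))
        s = nuisance_regress(s, NuisanceSet(rng.normal(size=(40, 2)), ["a", "b"]))
        f = ideal_bandpass(s, 0.01, 0.08)
        out = compute_peraf(f)
        ref = naive_peraf(f.data + f.voxel_mean[..., None], f.mask)
        np.testing.assert_allclose(out.data, ref, atol=1e-10)

    def test_mean_removed_series_without_stored_mean_rejected(self, rng):
        f = filtered(rng.normal(size=(1, 1, 1, 40)))
        with pytest.raises(ValueError, match="voxel mean"):
            compute_peraf(f)


class TestReHo:
    def test_identical_monotone_series_full_concordance(self):
        series = np.arange(10, dtype=float)
        vol = np.tile(series, (5, 5, 5, 1))
        out = compute_reho(filtered(vol), 27)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_hand_case_opposite_ranks_zero_w(self):
        pair = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert kendall_w(pair) == pytest.approx(0.0, abs=1e-12)

    def test_unfiltered_input_rejected(self, rng):
        with pytest.raises(PipelineOrderError):
            compute_reho(unfiltered(rng.normal(size=(3, 3, 3, 10))), 27)

    def test_range_zero_one(self, rng):
        vol = rng.normal(size=(5, 5, 5, 15))
        out = compute_reho(filtered(vol), 27)
        vals = out.in_mask()
        assert (vals >= 0).all() and (vals <= 1 + 1e-10).all()


class TestDC:
    def test_three_shared_one_orthogonal(self):
        t = np.arange(8, dtype=float)
        shared = np.sin(2 * np.pi * t / 8)
        ortho = np.cos(2 * np.pi * t / 8)  # exactly uncorrelated with shared
        vol = np.zeros((4, 1, 1, 8))
        vol[0, 0, 0] = shared
        vol[1, 0, 0] = 2.0 * shared + 1.0
        vol[2, 0, 0] = -0.0 + shared * 0.5
        vol[3, 0, 0] = ortho
        out = compute_dc(filtered(vol), 0.25)
        np.testing.assert_array_equal(out.data[:, 0, 0], [2, 2, 2, 0])

    def test_identical_voxels_full_degree(self, rng):
        series = rng.normal(size=12)
        vol = np.tile(series, (3, 3, 3, 1))
        out = compute_dc(filtered(vol), 0.25)
        np.testing.assert_array_equal(out.data, 26.0)

    def test_extreme_threshold_kills_noise_degree(self, rng):
        vol = rng.normal(size=(4, 4, 4, 40))
        out = compute_dc(filtered(vol), 0.9999)
        assert out.data.max() == 0

    def test_zero_variance_voxel_never_counted(self, rng):
        vol = rng.normal(size=(3, 1, 1, 20))
        vol[1] = 5.0  # constant
        out = compute_dc(filtered(vol), 0.25)
        assert out.data[1, 0, 0] == 0


class TestStandardize:
    def _map(self, values, mask=None):
        data = np.asarray(values, float).reshape(-1, 1, 1)
        if mask is None:
            mask = np.ones(data.shape, bool)
        return MetricMap(data, "ALFF", mask)

    def test_hand_case_division_convention(self):
        out = standardize_by_global_mean(self._map([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.data[:, 0, 0], [0.5, 1.0, 1.5])
        assert out.in_mask().mean() == pytest.approx(1.0)

    def test_idempotent_under_division(self):
        once = standardize_by_global_mean(self._map([1.0, 2.0, 3.0]))
        twice = standardize_by_global_mean(once)
        np.testing.assert_allclose(once.data, twice.data)

    def test_constant_map_goes_to_ones(self):
        out = standardize_by_global_mean(self._map([4.0, 4.0, 4.0]))
        np.testing.assert_allclose(out.in_mask(), 1.0)

    def test_zscore_mode(self, rng):
        vals = rng.normal(10, 2, size=20)
        out = standardize_by_global_mean(self._map(vals), mode="zscore")
        assert out.in_mask().mean() == pytest.approx(0.0, abs=1e-12)
        assert out.in_mask().std() == pytest.approx(1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            standardize_by_global_mean(self._map([-1.0, 1.0]))


class TestSmooth:
    def _impulse(self, n=15):
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        return MetricMap(data, "ALFF", np.ones((n, n, n), bool))

    def test_fwhm_zero_identity(self, rng):
        m = MetricMap(rng.normal(size=(5, 5, 5)), "ALFF", np.ones((5, 5, 5), bool))
        out = gaussian_smooth(m, 0.0)
        np.testing.assert_array_equal(out.data, m.data)
        assert out.smoothed

    def test_kernel_mass_conserved_for_interior_impulse(self):
        out = gaussian_smooth(self._impulse(), 4.0, voxel_size_mm=3.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_impulse_response_matches_closed_form(self):
        # fwhm 4 mm at 3 mm voxels -> sigma = 0.566 voxels
        out = gaussian_smooth(self._impulse(15), 4.0, voxel_size_mm=3.0)
        sigma = 4.0 / (3.0 * 2.0 * np.sqrt(2.0 * np.log(2.0)))
        assert sigma == pytest.approx(0.566, abs=5e-4)
        c = 7
        x = np.arange(15) - c
        g1 = np.exp(-x**2 / (2 * sigma**2))
        g1 /= g1.sum()
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        ok = expected > 1e-6
        np.testing.assert_allclose(out.data[ok], expected[ok], rtol=0.02)

    def test_smoothing_twice_raises(self):
        out = gaussian_smooth(self._impulse(), 4.0)
        with pytest.raises(PipelineOrderError):
            gaussian_smooth(out, 4.0)


class TestPlantedEffectRecovery:
    """Noiseless cohort: each planted effect kind dominates its metric.

    The window is 200 volumes so that chance in-band correlations (few
    independent spectral components at desk scale) do not swamp the planted
    structure; all three contrasts are deterministic properties of the signal
    model, not luck of one seed.
    """

    @pytest.fixture(scope="class")
    def noiseless_maps(self):
        from restiba.synthetic_cohort import (CohortSpec, EffectRegion,
                                              generate_cohort, hub_partner_mask,
                                              sphere_mask)
        from restiba.temporal_preprocess import PreprocConfig, preprocess_subject
        spec = CohortSpec(
            n_per_group=2, grid_shape=(16, 16, 16), n_volumes=200, noise_sd=0.0,
            motion_severity=0.0, seed=11,
            effects=[EffectRegion((4, 4, 4), 2, "amplitude", 2.0),
                     EffectRegion((11, 11, 4), 2, "synchrony", 1.0),
                     EffectRegion((4, 11, 11), 2, "hub", 1.0)])
        subjects, _ = generate_cohort(spec)
        s = subjects[0]  # reverter-like subject
        unf, filt, _ = preprocess_subject(s.bold, s.motion, s.wm_mask,
                                          s.csf_mask, PreprocConfig())
        regions = {e.kind: sphere_mask(spec.grid_shape, e.center, e.radius)
                   for e in spec.effects}
        regions["hub_partners"] = hub_partner_mask(spec, 2)
        return unf, filt, regions

    def test_amplitude_region_tops_alff(self, noiseless_maps):
        unf, _, regions = noiseless_maps
        alff = compute_alff(unf)
        region = regions["amplitude"] & alff.mask
        rest = alff.mask & ~regions["amplitude"]
        assert alff.data[region].mean() > np.percentile(alff.data[rest], 99)

    def test_synchrony_region_tops_reho(self, noiseless_maps):
        _, filt, regions = noiseless_maps
        reho = compute_reho(filt, 27)
        region = regions["synchrony"] & reho.mask
        rest = reho.mask & ~regions["synchrony"]
        assert reho.data[region].mean() > np.percentile(reho.data[rest], 99)

    def test_hub_region_tops_dc(self, noiseless_maps):
        # partner voxels carry the hub's latent course and are part of the
        # planted network, so the background excludes them
        _, filt, regions = noiseless_maps
        dc = compute_dc(filt, 0.25)
        region = regions["hub"] & dc.mask
        rest = dc.mask & ~regions["hub"] & ~regions["hub_partners"]
        assert dc.data[region].mean() > dc.data[rest].max()


class TestComputeAllMetrics:
    def test_both_peraf_branches_emitted(self, rng):
        from restiba.synthetic_cohort import CohortSpec, generate_cohort
        from restiba.temporal_preprocess import PreprocConfig, preprocess_subject
        spec = CohortSpec(n_per_group=2, grid_shape=(10, 10, 10), n_volumes=40, seed=2)
        subjects, _ = generate_cohort(spec)
        s = subjects[0]
        unf, filt, _ = preprocess_subject(s.bold, s.motion, s.wm_mask,
                                          s.csf_mask, PreprocConfig(n_discard=5))
        maps = compute_all_metrics(unf, filt, MetricConfig())
        assert set(maps) == {"ALFF_std_sm", "fALFF_std_sm", "PerAF_std_sm",
                             "ReHo_std_sm", "DC_std_sm", "PerAF_sm"}
        assert maps["PerAF_sm"].smoothed and not maps["PerAF_sm"].standardized
        assert maps["PerAF_std_sm"].standardized and maps["PerAF_std_sm"].smoothed
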