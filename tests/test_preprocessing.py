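"""Pre-treatment contracts: raw screening, averaging, AsLS baseline,
water-band normalization and region selection."""

import numpy as np
import pytest

from ramcal.preprocessing import (DEFAULT_REGIONS, PreprocessConfig, Spectrum,
                                  asls_baseline, average_replicates,
                                  correct_baseline, normalize_water_band,
                                  preprocess_pipeline, region_mask, screen_raw,
                                  select_regions, subtract_dark)
from ramcal.synthetic_data import (DEFAULT_AXIS, NoiseModel,
                                   PureComponentLibrary,
                                   corrupt_with_artifacts, synthesize_spectrum)

CFG = PreprocessConfig()


def _spectrum(intensity, axis=None, **meta):
    axis = DEFAULT_AXIS if axis is None else axis
    return Spectrum(axis, intensity, meta)


class TestScreenRaw:
    def test_all_zero_fails_as_empty_chamber(self):
        ok, reason = screen_raw(_spectrum(np.zeros(DEFAULT_AXIS.size)), CFG)
        assert not ok and reason == "empty_chamber"

    def test_default_synthetic_spectrum_passes(self):
        spec = synthesize_spectrum({"glucose": 5.0}, PureComponentLibrary(),
                                   NoiseModel(seed=0), batch_age=3)
        ok, reason = screen_raw(spec, CFG)
        assert ok and reason is None

    def test_strong_bubble_attenuation_fails(self, small_records):
        out, idx = corrupt_with_artifacts(small_records, fraction_bubble=0.1,
                                          attenuation=0.01, seed=3)
        for i in idx["bubble"]:
            avg = average_replicates(out[i].replicate_spectra())
            ok, reason = screen_raw(avg, CFG)
            assert not ok and reason in ("empty_chamber", "weak_water_band")


class TestDarkAndAveraging:
    def test_dark_subtraction_pointwise(self):
        y = np.linspace(1, 2, DEFAULT_AXIS.size)
        spec = _spectrum(y)
        assert np.array_equal(
            subtract_dark(spec, _spectrum(np.zeros_like(y))).intensity, y)
        np.testing.assert_allclose(
            subtract_dark(spec, spec).intensity, 0.0)
        np.testing.assert_allclose(
            subtract_dark(spec, _spectrum(np.full_like(y, 0.25))).intensity,
            y - 0.25)

    def test_dark_axis_mismatch_rejected(self):
        spec = _spectrum(np.ones(DEFAULT_AXIS.size))
        dark = Spectrum(DEFAULT_AXIS[:-1], np.ones(DEFAULT_AXIS.size - 1), {})
        with pytest.raises(ValueError):
            subtract_dark(spec, dark)

    def test_average_of_identical_replicates_is_identity(self):
        y = np.linspace(0, 1, DEFAULT_AXIS.size)
        spectra = [_spectrum(y, sample_id="s", averages=60) for _ in range(5)]
        avg = average_replicates(spectra)
        np.testing.assert_allclose(avg.intensity, y, rtol=1e-15, atol=1e-16)
        assert avg.meta["averages"] == 300

    def test_mean_of_two_values(self):
        s0 = _spectrum(np.zeros(DEFAULT_AXIS.size), sample_id="s")
        s2 = _spectrum(np.full(DEFAULT_AXIS.size, 2.0), sample_id="s")
        np.testing.assert_array_equal(average_replicates([s0, s2]).intensity, 1.0)

    def test_mixed_sample_ids_rejected(self):
        a = _spectrum(np.ones(DEFAULT_AXIS.size), sample_id="a")
        b = _spectrum(np.ones(DEFAULT_AXIS.size), sample_id="b")
        with pytest.raises(ValueError):
            average_replicates([a, b])

    def test_noise_reduction_scales_as_sqrt_n(self):
        """Averaging five i.i.d.-noise replicates reduces the residual sd by
        about sqrt(5)."""
        rng = np.random.default_rng(0)
        sigma, n_channels = 0.5, 500
        clean = np.zeros(n_channels)
        axis = np.arange(n_channels, dtype=float)
        reps = [_spectrum(clean + rng.normal(0, sigma, n_channels), axis=axis,
                          sample_id="s") for _ in range(5)]
        resid_sd = average_replicates(reps).intensity.std()
        assert resid_sd == pytest.approx(sigma / np.sqrt(5), rel=0.20)


class TestAslsBaseline:
    def test_constant_vector_reproduced(self):
        base = asls_baseline(np.full(800, 7.0))
        np.testing.assert_allclose(base, 7.0, atol=1e-6 * 7.0)

    def test_peak_on_ramp_recovered_within_5_percent(self):
        x = np.arange(1000, dtype=float)
        ramp = 5.0 + 0.01 * x
        peak = 10.0 * np.exp(-0.5 * ((x - 500) / 15) ** 2)
        corrected = ramp + peak - asls_baseline(ramp + peak, lam=1e5, p=0.001)
        assert corrected[500] == pytest.approx(10.0, rel=0.05)

    def test_asymmetry_pushes_baseline_down(self):
        rng = np.random.default_rng(1)
        y = np.sin(np.linspace(0, 4, 600)) + rng.normal(0, 0.2, 600)
        above = []
        for p in (0.5, 0.05, 0.001):
            z = asls_baseline(y, lam=1e4, p=p)
            above.append((y > z).mean())
        assert above[0] < above[1] < above[2]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            asls_baseline(np.array([1.0, np.nan, 2.0, 3.0]))
        with pytest.raises(ValueError):
            asls_baseline(np.ones(10), lam=-1.0)
        with pytest.raises(ValueError):
            asls_baseline(np.ones(10), p=1.5)

    def test_zero_spectrum_corrects_to_zero(self):
        spec = _spectrum(np.zeros(DEFAULT_AXIS.size))
        np.testing.assert_allclose(correct_baseline(spec, CFG).intensity,
                                   0.0, atol=1e-9)


class TestWaterBandNormalization:
    spec = synthesize_spectrum({"lactate": 4.0}, PureComponentLibrary(),
                               NoiseModel(detector_sd=0, gain_jitter_sd=0),
                               batch_age=2)

    def _stat(self, spectrum, cfg=CFG):
        from ramcal.preprocessing import _water_band_statistic
        return _water_band_statistic(spectrum, cfg)

    def test_band_statistic_becomes_one(self):
        assert self._stat(normalize_water_band(self.spec, CFG)) == \
            pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        scaled = Spectrum(self.spec.axis, 7.3 * self.spec.intensity, {})
        np.testing.assert_allclose(
            normalize_water_band(scaled, CFG).intensity,
            normalize_water_band(self.spec, CFG).intensity, atol=1e-12)

    def test_idempotence(self):
        once = normalize_water_band(self.spec, CFG)
        twice = normalize_water_band(once, CFG)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-12)

    def test_height_statistic_option(self):
        cfg = PreprocessConfig(water_statistic="height")
        out = normalize_water_band(self.spec, cfg)
        assert self._stat(out, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_statistic_rejected(self):
        with pytest.raises(ValueError):
            normalize_water_band(
                _spectrum(np.full(DEFAULT_AXIS.size, -1.0)), CFG)

    def test_gain_jitter_removed(self):
        """Two spectra identical except multiplicative gain coincide after
        normalization."""
        lib, noise = PureComponentLibrary(), NoiseModel(detector_sd=0,
                                                        gain_jitter_sd=0)
        a = synthesize_spectrum({"glucose": 3}, lib, noise, 5, gain=1.0)
        b = synthesize_spectrum({"glucose": 3}, lib, noise, 5, gain=1.37)
        np.testing.assert_allclose(
            normalize_water_band(a, CFG).intensity,
            normalize_water_band(b, CFG).intensity, atol=1e-9)


class TestRegions:
    def test_full_axis_region_is_identity(self):
        cfg = PreprocessConfig(regions={"glucose": [(0.0, 1e5)]})
        sub, ax = select_regions(self.make_spec(), "glucose", cfg)
        assert sub.size == DEFAULT_AXIS.size

    def test_two_windows_channel_count(self):
        # 2 cm^-1 grid: [500, 520] has 11 channels, [1000, 1008] has 5
        cfg = PreprocessConfig(regions={"glucose": [(500, 520), (1000, 1008)]})
        sub, ax = select_regions(self.make_spec(), "glucose", cfg)
        assert sub.size == 16
        assert np.all(np.diff(ax) > 0)

    def test_unknown_analyte_and_empty_intersection(self):
        with pytest.raises(KeyError):
            select_regions(self.make_spec(), "caffeine", CFG)
        cfg = PreprocessConfig(regions={"glucose": [(9000, 9100)]})
        with pytest.raises(ValueError):
            select_regions(self.make_spec(), "glucose", cfg)

    @staticmethod
    def make_spec():
        return _spectrum(np.ones(DEFAULT_AXIS.size))

    def test_default_regions_cover_all_library_bands(self):
        lib = PureComponentLibrary()
        for analyte, bands in lib.bands.items():
            mask = region_mask(DEFAULT_AXIS, DEFAULT_REGIONS[analyte])
            for center, _sigma, _amp in bands:
                assert mask[np.argmin(np.abs(DEFAULT_AXIS - center))], \
                    (analyte, center)


class TestPipeline:
    def test_rows_align_and_failures_logged(self, small_records):
        out, idx = corrupt_with_artifacts(small_records, fraction_empty=0.1,
                                          seed=4)
        X, meta, log = preprocess_pipeline(out)
        assert X.shape[0] == len(meta)
        assert (log.verdict == "fail").sum() == len(idx["empty"])
        failed_ids = set(log.loc[log.verdict == "fail", "record_id"])
        assert failed_ids == {out[i].record_id for i in idx["empty"]}
        assert not failed_ids & set(meta.record_id)

    def test_all_failing_records_rejected(self, small_records):
        out, _ = corrupt_with_artifacts(small_records, fraction_empty=1.0,
                                        seed=5)
        with pytest.raises(ValueError):
            preprocess_pipeline(out)

    def test_gain_jitter_fully_removed_by_pipeline(self, small_design):
        """Noise-free data differing only by per-sample gain: after baseline
        correction and normalization the non-analyte channels carry no
        inter-sample variation beyond numerical noise."""
        from ramcal.experiment_design import build_schedule
        from ramcal.synthetic_data import generate_dataset
        noise = NoiseModel(detector_sd=0.0, gain_jitter_sd=0.08,
                           fluor_growth_per_day=0.0, reference_cv={}, seed=0)
        schedule = build_schedule(6, 1, frozenset())
        recs = generate_dataset(small_design, noise=noise, schedule=schedule,
                                seed=0)
        X, meta, _ = preprocess_pipeline(recs)
        mask = np.ones(DEFAULT_AXIS.size, dtype=bool)
        lib = PureComponentLibrary()
        for bands in lib.bands.values():
            for c, s, _a in bands:
                mask &= ~((DEFAULT_AXIS > c - 8 * s) & (DEFAULT_AXIS < c + 8 * s))
        spread = np.ptp(X[:, mask], axis=0)
        assert spread.max() < 1e-9

    def test_fluorescence_growth_mostly_removed(self, small_design):
        """Day-varying fluorescence is removed down to small AsLS leakage:
        residual inter-sample spread at non-analyte channels stays two
        orders of magnitude below the analyte signal scale."""
        from ramcal.experiment_design import build_schedule
        from ramcal.synthetic_data import generate_dataset
        noise = NoiseModel(detector_sd=0.0, gain_jitter_sd=0.05,
                           reference_cv={}, seed=0)
        schedule = build_schedule(6, 6, frozenset())
        recs = generate_dataset(small_design, noise=noise, schedule=schedule,
                                seed=0)
        X, meta, _ = preprocess_pipeline(recs)
        mask = np.ones(DEFAULT_AXIS.size, dtype=bool)
        lib = PureComponentLibrary()
        for bands in lib.bands.values():
            for c, s, _a in bands:
                mask &= ~((DEFAULT_AXIS > c - 8 * s) & (DEFAULT_AXIS < c + 8 * s))
        mask &= (DEFAULT_AXIS > 300) & (DEFAULT_AXIS < 3100)
        spread = np.ptp(X[:, mask], axis=0).max()
        assert spread < 1e-2 * np.abs(X).max()
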