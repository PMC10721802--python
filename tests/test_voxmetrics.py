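"""Voxel metric unit tests: filters, confound regression, fALFF/LCOR/ICC.

Expected values come from independent oracles: FFT amplitude comparison for
the band-pass, OLS normal equations for confound regression, discrete
spectrum concentration for fALFF, brute-force correlation means for LCOR,
and the E[r^2] = 1/(T-1) null for ICC.
"""

import numpy as np
import pytest

from mcifmri import (
    Band,
    BoldSeries,
    bandpass_filter,
    compute_falff,
    compute_icc,
    compute_lcor,
    regress_confounds,
)
from tests.conftest import make_series

TR = 2.0
T = 300
TIME = np.arange(T) * TR


def sinusoid_series(freq_hz: float, shape=(2, 2, 1)) -> BoldSeries:
    wave = np.sin(2 * np.pi * freq_hz * TIME)
    data = np.broadcast_to(wave, shape + (T,)).copy()
    return make_series(data, tr_seconds=TR)


def fft_amplitude(x: np.ndarray, freq_hz: float) -> float:
    amp = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=TR)
    return amp[np.argmin(np.abs(freqs - freq_hz))]


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,comparison",
        [(0.05, "preserved"), (0.2, "attenuated")],
    )
    def test_sinusoid_pass_and_stop(self, freq, comparison):
        series = sinusoid_series(freq)
        out = bandpass_filter(series, Band(0.008, 0.09))
        ratio = fft_amplitude(out.data[0, 0, 0], freq) / fft_amplitude(
            series.data[0, 0, 0], freq
        )
        if comparison == "preserved":
            assert ratio >= 0.9
        else:
            assert ratio <= 0.1

    def test_zero_series_maps_to_zero(self):
        series = make_series(np.zeros((2, 1, 1, T)), tr_seconds=TR)
        out = bandpass_filter(series)
        assert np.allclose(out.data, 0.0)

    def test_output_is_zero_mean_and_same_length(self):
        rng = np.random.default_rng(0)
        series = make_series(rng.standard_normal((2, 2, 2, T)), tr_seconds=TR)
        out = bandpass_filter(series)
        assert out.data.shape == series.data.shape
        assert np.allclose(out.data.mean(axis=-1), 0.0, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        series = sinusoid_series(0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(series, Band(0.008, 0.3))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            make_series(np.zeros((1, 1, 1, 32)), tr_seconds=TR)


class TestConfoundRegression:
    def test_series_equal_to_confound_vanishes(self, rng):
        conf = rng.standard_normal((T, 1))
        data = np.broadcast_to(conf[:, 0], (2, 1, 1, T)).copy()
        out = regress_confounds(make_series(data, tr_seconds=TR), conf)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_confounds_leave_demeaned_signal(self):
        # sinusoids at distinct DFT bins are exactly orthogonal over the window
        sig = np.sin(2 * np.pi * 5 * np.arange(T) / T)
        conf = np.cos(2 * np.pi * 11 * np.arange(T) / T)[:, None]
        series = make_series(sig.reshape(1, 1, 1, T), tr_seconds=TR)
        out = regress_confounds(series, conf)
        demeaned = sig - sig.mean()
        assert np.allclose(out.data[0, 0, 0], demeaned, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        series = make_series(rng.standard_normal((3, 2, 1, T)), tr_seconds=TR)
        conf = rng.standard_normal((T, 4))
        out = regress_confounds(series, conf)
        resid = out.data.reshape(-1, T)
        design = np.column_stack([np.ones(T), conf])
        assert np.max(np.abs(resid @ design)) < 1e-6

    def test_collinear_design_names_columns(self, rng):
        import pandas as pd

        a = rng.standard_normal(T)
        conf = pd.DataFrame({"wm": a, "csf": rng.standard_normal(T), "wm_copy": a})
        series = make_series(rng.standard_normal((1, 1, 1, T)), tr_seconds=TR)
        with pytest.raises(ValueError, match="wm"):
            regress_confounds(series, conf)


class TestFalff:
    def test_in_band_sinusoid_concentrates(self):
        vmap = compute_falff(sinusoid_series(0.05), Band(0.008, 0.09))
        assert np.all(vmap.values >= 0.95)

    def test_out_of_band_sinusoid_excluded(self):
        vmap = compute_falff(sinusoid_series(0.2), Band(0.008, 0.09))
        assert np.all(vmap.values <= 0.05)

    def test_constant_series_is_zero(self):
        series = make_series(np.full((2, 1, 1, T), 7.0), tr_seconds=TR)
        vmap = compute_falff(series)
        assert np.all(vmap.values == 0.0)

    def test_band_partition_sums_to_one(self, rng):
        # complementary bands partition the positive frequencies
        series = make_series(rng.standard_normal((2, 2, 1, T)), tr_seconds=TR)
        nyq = 1.0 / (2 * TR)
        split = 0.0503  # off any DFT bin for T=300, TR=2
        low = compute_falff(series, Band(0.0, split)).values
        high = compute_falff(series, Band(split + 1e-9, nyq)).values
        assert np.allclose(low + high, 1.0, atol=1e-10)


class TestLcor:
    def test_identical_series_give_one(self, rng):
        wave = rng.standard_normal(T)
        data = np.broadcast_to(wave, (3, 3, 1, T)).copy()
        vmap = compute_lcor(make_series(data, tr_seconds=TR))
        assert np.allclose(vmap.values, 1.0, atol=1e-10)

    def test_independent_noise_averages_near_zero(self, rng):
        series = make_series(rng.standard_normal((4, 4, 2, T)), tr_seconds=TR)
        vmap = compute_lcor(series)
        assert abs(vmap.values.mean()) <= 0.05

    def test_anticorrelated_pair_gives_minus_one(self, rng):
        wave = rng.standard_normal(T)
        data = np.stack([wave, -wave]).reshape(2, 1, 1, T)
        vmap = compute_lcor(make_series(data, tr_seconds=TR))
        assert np.allclose(vmap.values, -1.0, atol=1e-10)

    def test_wide_kernel_matches_brute_force_mean_correlation(self, rng):
        shape = (4, 4, 3)
        data = rng.standard_normal(shape + (T,))
        series = make_series(data, tr_seconds=TR)
        vmap = compute_lcor(series, kernel_fwhm_mm=1e6, truncate_factor=1.0)
        flat = data.reshape(-1, T)
        corr = np.corrcoef(flat)
        oracle = (corr.sum(axis=1) - 1.0) / (flat.shape[0] - 1)
        assert np.allclose(vmap.values.ravel(), oracle, atol=1e-8)

    def test_kernel_smaller_than_voxel_rejected(self, rng):
        series = make_series(rng.standard_normal((2, 2, 1, T)), voxel_size_mm=(30, 30, 30))
        with pytest.raises(ValueError, match="kernel"):
            compute_lcor(series, kernel_fwhm_mm=25.0)


class TestIcc:
    def test_identical_series_give_one_both_variants(self, rng):
        wave = rng.standard_normal(T)
        data = np.broadcast_to(wave, (2, 2, 2, T)).copy()
        series = make_series(data, tr_seconds=TR)
        assert np.allclose(compute_icc(series, variant="power").values, 1.0, atol=1e-10)
        assert np.allclose(compute_icc(series, variant="degree").values, 1.0, atol=1e-10)

    def test_independent_noise_matches_null_expectation(self, rng):
        # E[r^2] = 1/(T-1) for independent Gaussian series
        series = make_series(rng.standard_normal((6, 6, 3, T)), tr_seconds=TR)
        vmap = compute_icc(series, variant="power")
        expected = 1.0 / (T - 1)
        assert abs(vmap.values.mean() - expected) <= 0.5 * expected

    def test_two_anticorrelated_blocks(self, rng):
        # blocks share +wave / -wave: all |r| = 1, so power = 1 everywhere
        # while the degree variant counts only the within-block half
        wave = rng.standard_normal(T)
        data = np.empty((4, 2, 1, T))
        data[:, 0, 0, :] = wave
        data[:, 1, 0, :] = -wave
        series = make_series(data, tr_seconds=TR)
        assert np.allclose(compute_icc(series, variant="power").values, 1.0, atol=1e-10)
        deg = compute_icc(series, variant="degree", degree_threshold=0.25)
        assert np.allclose(deg.values, 3.0 / 7.0, atol=1e-10)

    def test_single_voxel_mask_rejected(self, rng):
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, 0, 0] = True
        series = make_series(rng.standard_normal((2, 2, 1, T)), brain_mask=mask)
        with pytest.raises(ValueError, match="at least 2"):
            compute_icc(series)


class TestScaleInvariance:
    """fALFF, LCOR and ICC are ratio/correlation based: positive rescaling of
    any voxel's series must leave every map unchanged."""

    @pytest.mark.parametrize("metric", ["falff", "lcor", "icc"])
    def test_positive_rescaling_is_invariant(self, metric, rng):
        data = rng.standard_normal((3, 3, 2, T))
        scales = rng.uniform(0.1, 10.0, size=(3, 3, 2, 1))
        a = make_series(data, tr_seconds=TR)
        b = make_series(data * scales, tr_seconds=TR)
        fn = {
            "falff": compute_falff,
            "lcor": compute_lcor,
            "icc": compute_icc,
        }[metric]
        assert np.allclose(fn(a).values, fn(b).values, atol=1e-9)
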