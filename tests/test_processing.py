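"""Spectral processing chain: transforms, phasing, baseline, referencing."""

import numpy as np
import pytest

from nmrprofile import simulate as sim
from nmrprofile.model import InvalidParameterError, Spectrum, synthesize_mixture
from nmrprofile.processing import (
    FID,
    PhaseParams,
    ProcessingParams,
    ReferencingError,
    apply_phase,
    autophase,
    correct_baseline,
    detect_baseline,
    estimate_noise,
    fourier_transform,
    hilbert_reconstruct,
    process,
    reference_shift,
    smooth,
    spectrum_to_fid,
    zero_fill,
)


def _noisy_mixture(n=16384, n_compounds=10, sigma=5.0, lib_seed=3, seed=5):
    axis = sim.default_axis(n)
    lib = sim.generate_library(n_compounds, seed=lib_seed)
    truth = sim.sample_truth(lib, 0.9, (50, 2000), seed=seed - 1)
    clean = synthesize_mixture(lib, truth, axis)
    rng = np.random.default_rng(seed)
    noisy = Spectrum(axis, clean.real + rng.normal(0, sigma, n), frequency=500.0)
    return lib, truth, clean, noisy, sigma


class TestZeroFill:
    def test_pads_with_zeros(self):
        fid = FID(np.ones(1000, dtype=complex), 1e-4)
        out = zero_fill(fid, 2048)
        assert out.n_points == 2048
        assert not out.points[1000:].any()
        assert out.dwell_time == fid.dwell_time

    def test_default_next_power_of_two(self):
        fid = FID(np.ones(1000, dtype=complex), 1e-4)
        assert zero_fill(fid).n_points == 2048

    def test_identity_and_error(self):
        fid = FID(np.arange(8, dtype=complex), 1e-4)
        np.testing.assert_array_equal(zero_fill(fid, 8).points, fid.points)
        with pytest.raises(InvalidParameterError):
            zero_fill(fid, 4)

    def test_interpolates_original_grid(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=256) * np.exp(-np.arange(256) / 50.0) + 0j
        fid = FID(pts, 1e-4)
        orig = np.fft.fft(fid.points)
        filled = np.fft.fft(zero_fill(fid, 512).points)
        np.testing.assert_allclose(filled[::2], orig, atol=1e-9 * np.abs(orig).max())


class TestFourier:
    def test_decaying_exponential_gives_lorentzian(self):
        # analytic: FT of exp(i w t - t/tau) is a Lorentzian at w of
        # half-width 1/(2 pi tau) Hz
        n, dwell, freq = 16384, 1.0 / 6000.0, 500.0
        t = np.arange(n) * dwell
        f_hz, tau = 700.0, 0.15  # fully decayed within the acquisition window
        fid = FID(np.exp(2j * np.pi * f_hz * t - t / tau), dwell, freq)
        spec = fourier_transform(fid)
        apex_ppm = spec.ppm_axis[np.argmax(spec.real)]
        assert apex_ppm == pytest.approx(f_hz / freq, abs=2 * spec.spacing)
        half = spec.real.max() / 2
        width_pts = np.count_nonzero(spec.real > half)
        fwhm_hz = width_pts * spec.spacing * freq
        assert fwhm_hz == pytest.approx(1.0 / (np.pi * tau), rel=0.25)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        fid = FID(rng.normal(size=1024) + 1j * rng.normal(size=1024), 1e-4, 500.0, 4.0)
        back = spectrum_to_fid(fourier_transform(fid))
        np.testing.assert_allclose(back.points, fid.points, atol=1e-10)
        assert back.dwell_time == pytest.approx(fid.dwell_time)

    def test_zero_fid_zero_spectrum(self):
        spec = fourier_transform(FID(np.zeros(64, dtype=complex), 1e-4))
        assert not spec.real.any() and not spec.imag.any()


class TestHilbert:
    def test_real_part_preserved(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        h = hilbert_reconstruct(spec)
        np.testing.assert_allclose(h.real, spec.real, atol=1e-9 * spec.real.max())

    def test_dispersive_lineshape(self):
        # imaginary channel of an absorptive Lorentzian is the analytic
        # dispersive shape -h * g * dx / (dx^2 + g^2)
        axis = sim.default_axis(8192)
        from nmrprofile.model import Peak, eval_lorentzian

        p = Peak(height=100.0, center=5.0, fwhm=0.02)
        spec = Spectrum(axis, eval_lorentzian(p, 0.0, axis))
        h = hilbert_reconstruct(spec)
        g = 0.01
        disp = -100.0 * g * (axis - 5.0) / ((axis - 5.0) ** 2 + g * g)
        interior = (axis > 2.0) & (axis < 8.0)
        rms = np.sqrt(np.mean((h.imag[interior] - disp[interior]) ** 2))
        assert rms < 0.01 * 100.0

    def test_phase_then_unphase_is_identity(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = hilbert_reconstruct(synthesize_mixture(lib, truth, axis))
        params = PhaseParams(0.8, -0.4)
        back = apply_phase(apply_phase(spec, params), PhaseParams(-0.8, 0.4))
        np.testing.assert_allclose(back.real, spec.real, atol=1e-9 * np.abs(spec.real).max())


class TestApplyPhase:
    def test_zero_phase_identity(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = hilbert_reconstruct(synthesize_mixture(lib, truth, axis))
        out = apply_phase(spec, PhaseParams(0.0, 0.0))
        np.testing.assert_array_equal(out.real, spec.real)

    def test_pi_negates_real(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = hilbert_reconstruct(synthesize_mixture(lib, truth, axis))
        out = apply_phase(spec, PhaseParams(np.pi, 0.0))
        np.testing.assert_allclose(out.real, -spec.real, atol=1e-9 * spec.real.max())

    def test_requires_complex(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        with pytest.raises(InvalidParameterError, match="hilbert"):
            apply_phase(spec, PhaseParams(0.1, 0.0))


class TestAutophase:
    def test_already_phased_recovers_zero(self):
        _, _, _, noisy, _ = _noisy_mixture()
        spec = hilbert_reconstruct(noisy)
        _, params, diag = autophase(spec, seed=0)
        assert abs(params.phi0) < 0.02
        assert diag.n_peaks > 0

    def test_recovers_known_distortion(self):
        _, _, _, noisy, _ = _noisy_mixture()
        fid = sim.distort_to_fid(noisy, 0.7, 0.3, baseline=None)
        _, params, _ = autophase(fourier_transform(fid), seed=0)
        assert params.phi0 == pytest.approx(0.7, abs=0.02)
        assert params.phi1 == pytest.approx(0.3, abs=0.05)

    def test_objective_scale_invariant(self):
        _, _, _, noisy, _ = _noisy_mixture()
        fid = sim.distort_to_fid(noisy, -0.4, 0.2, baseline=None)
        spec = fourier_transform(fid)
        scaled = spec.copy()
        scaled.real *= 37.0
        scaled.imag *= 37.0
        _, p1, _ = autophase(spec, seed=0)
        _, p2, _ = autophase(scaled, seed=0)
        assert p1.phi0 == pytest.approx(p2.phi0, abs=1e-6)
        assert p1.phi1 == pytest.approx(p2.phi1, abs=1e-6)

    def test_no_peaks_warns_and_returns_zero(self):
        rng = np.random.default_rng(0)
        spec = Spectrum(sim.default_axis(4096), rng.normal(0, 1, 4096))
        _, params, diag = autophase(spec, seed=0)
        assert (params.phi0, params.phi1) == (0.0, 0.0)
        assert diag.warning is not None


class TestEstimateNoise:
    def test_pure_gaussian(self):
        # Monte Carlo: across realizations the estimator is unbiased to 5%
        ests = []
        for s in range(10):
            rng = np.random.default_rng(s)
            spec = Spectrum(sim.default_axis(2**14), rng.normal(0, 1.0, 2**14))
            ests.append(estimate_noise(spec))
        assert np.mean(ests) == pytest.approx(1.0, rel=0.05)

    def test_noise_free_is_tiny(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        assert estimate_noise(spec) < 1e-6 * spec.real.max()

    def test_robust_to_tall_peak(self):
        rng = np.random.default_rng(13)
        axis = sim.default_axis(2**14)
        noise = rng.normal(0, 1.0, 2**14)
        base = estimate_noise(Spectrum(axis, noise.copy()))
        from nmrprofile.model import Peak, eval_lorentzian

        withpeak = noise + eval_lorentzian(Peak(5000.0, 5.0, 0.01), 0.0, axis)
        spiked = estimate_noise(Spectrum(axis, withpeak))
        assert spiked == pytest.approx(base, rel=0.10)


class TestBaseline:
    def test_flat_noise_mostly_flagged(self):
        rng = np.random.default_rng(3)
        spec = Spectrum(sim.default_axis(8192), rng.normal(0, 1.0, 8192))
        estimate_noise(spec)
        mask = detect_baseline(spec)
        assert mask.mean() > 0.99

    def test_peak_region_not_flagged(self):
        from nmrprofile.model import Peak, eval_lorentzian

        rng = np.random.default_rng(4)
        axis = sim.default_axis(8192)
        peak = eval_lorentzian(Peak(500.0, 5.0, 0.02), 0.0, axis)
        spec = Spectrum(axis, peak + rng.normal(0, 1.0, 8192))
        estimate_noise(spec)
        mask = detect_baseline(spec)
        near = np.abs(axis - 5.0) < 3 * 0.02
        assert not mask[near].any()

    def test_mask_is_fixed_point(self):
        _, _, _, noisy, _ = _noisy_mixture(n=8192)
        estimate_noise(noisy)
        m1 = detect_baseline(noisy)
        m2 = detect_baseline(noisy)
        assert np.count_nonzero(m1 ^ m2) < 8192 * 0.001

    def test_known_drift_recovered(self):
        lib, truth, clean, noisy, sigma = _noisy_mixture(n=16384)
        axis = noisy.ppm_axis
        drift = 80 * ((axis / 10) ** 3 - 0.5 * (axis / 10) + 0.2 * np.cos(axis / 3.0))
        drifted = Spectrum(axis, noisy.real + drift, frequency=500.0)
        estimate_noise(drifted)
        corrected = correct_baseline(drifted)
        resid = corrected.real - clean.real
        base_pts = clean.real < 0.5 * sigma
        rms = np.sqrt(np.mean(resid[base_pts] ** 2))
        assert rms < 2 * sigma

    def test_zero_drift_nearly_unchanged(self):
        # on a flat noisy spectrum the fitted baseline curve stays within the
        # noise scale everywhere
        rng = np.random.default_rng(8)
        spec = Spectrum(sim.default_axis(8192), rng.normal(0, 1.0, 8192))
        estimate_noise(spec)
        corrected = correct_baseline(spec)
        assert np.abs(corrected.real - spec.real).max() < 1.0

    def test_idempotent_within_noise(self):
        lib, truth, clean, noisy, sigma = _noisy_mixture(n=8192)
        axis = noisy.ppm_axis
        drift = 40 * np.cos(axis / 2.0)
        drifted = Spectrum(axis, noisy.real + drift, frequency=500.0)
        estimate_noise(drifted)
        once = correct_baseline(drifted)
        estimate_noise(once)
        twice = correct_baseline(once)
        assert np.sqrt(np.mean((twice.real - once.real) ** 2)) < 2 * sigma


class TestSmooth:
    def test_none_is_identity(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        np.testing.assert_array_equal(smooth(spec, "none").real, spec.real)

    def test_savgol_reproduces_polynomial(self):
        axis = sim.default_axis(1024)
        poly = 3.0 + 2.0 * axis - 0.5 * axis**2 + 0.01 * axis**3
        spec = Spectrum(axis, poly)
        out = smooth(spec, "savitzky_golay", window=9, polyorder=3)
        np.testing.assert_allclose(out.real[5:-5], poly[5:-5], atol=1e-9 * np.abs(poly).max())

    def test_gaussian_broadening_preserves_area(self):
        from nmrprofile.model import Peak, eval_lorentzian

        axis = sim.default_axis(16384)
        spec = Spectrum(axis, eval_lorentzian(Peak(100.0, 5.0, 0.01), 0.0, axis))
        out = smooth(spec, "gaussian_broaden", broaden_sigma_ppm=0.002)
        interior = (axis > 3.0) & (axis < 7.0)
        a0 = np.trapezoid(spec.real[interior], axis[interior])
        a1 = np.trapezoid(out.real[interior], axis[interior])
        assert a1 == pytest.approx(a0, rel=1e-3)

    def test_bad_params_rejected(self, small_mixture):
        lib, truth, axis = small_mixture
        spec = synthesize_mixture(lib, truth, axis)
        with pytest.raises(InvalidParameterError):
            smooth(spec, "savitzky_golay", window=4)
        with pytest.raises(InvalidParameterError):
            smooth(spec, "what")


class TestReferenceShift:
    def test_offset_peak_pulled_to_zero(self):
        from nmrprofile.model import Peak, eval_lorentzian

        axis = sim.default_axis(16384)
        rng = np.random.default_rng(5)
        y = eval_lorentzian(Peak(4000.0, 0.013, 0.0025), 0.0, axis) + rng.normal(0, 1, axis.size)
        spec = Spectrum(axis, y)
        estimate_noise(spec)
        out, offset = reference_shift(spec)
        assert offset == pytest.approx(-0.013, abs=2e-4)
        apex = out.ppm_axis[np.argmax(out.real)]
        assert abs(apex) < out.spacing

    def test_already_referenced_small_correction(self):
        from nmrprofile.model import Peak, eval_lorentzian

        axis = sim.default_axis(16384)
        spec = Spectrum(axis, eval_lorentzian(Peak(4000.0, 0.0, 0.0025), 0.0, axis))
        spec.noise_sigma = 1.0
        _, offset = reference_shift(spec)
        assert abs(offset) < spec.spacing

    def test_no_reference_peak_raises(self):
        rng = np.random.default_rng(6)
        spec = Spectrum(sim.default_axis(4096), rng.normal(0, 1.0, 4096))
        estimate_noise(spec)
        with pytest.raises(ReferencingError):
            reference_shift(spec)


class TestFullChain:
    def test_end_to_end_recovery(self):
        """Distort a known noisy spectrum into a FID, process it, and demand
        the clean spectrum back: residual RMS below 3 sigma in signal-free
        regions and apex errors below 2% for strong (>= 500 sigma) peaks."""
        lib, truth, clean, noisy, sigma = _noisy_mixture(n=16384, lib_seed=20, seed=100)
        fid = sim.distort_to_fid(noisy, 0.45, -0.25, baseline=30 * sigma, seed=0)
        spec, report = process(fid)
        assert report.phase.phi0 == pytest.approx(0.45, abs=0.05)
        assert report.phase.phi1 == pytest.approx(-0.25, abs=0.1)
        resid = spec.real - clean.real
        base_pts = clean.real < 0.5 * sigma
        assert np.sqrt(np.mean(resid[base_pts] ** 2)) < 3 * sigma
        axis = spec.ppm_axis
        for comp, cl in lib.clusters():
            rho = truth.concentrations.get(comp.name, 0.0)
            if rho == 0.0:
                continue
            for pk in cl.peaks:
                i = np.argmin(np.abs(noisy.ppm_axis - (pk.center + truth.shifts[cl.cluster_id])))
                if clean.real[i] < 500 * sigma:
                    continue
                assert abs(resid[i]) / clean.real[i] < 0.02

    def test_deterministic(self):
        _, _, _, noisy, sigma = _noisy_mixture(n=8192)
        fid = sim.distort_to_fid(noisy, 0.2, 0.1, baseline=20 * sigma, seed=1)
        s1, _ = process(fid, ProcessingParams(seed=3))
        s2, _ = process(fid, ProcessingParams(seed=3))
        np.testing.assert_array_equal(s1.real, s2.real)
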