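"""Phasor transform, universal-circle geometry, calibration, lifetimes."""

import numpy as np
import pytest

import phasorprint as pp
from phasorprint.phasor import bin_correction_factor

from conftest import noise_free_cube

RATE = 8.0e7
OMEGA = 2 * np.pi * RATE * 1e-9  # rad/ns


def brute_force_phasor(counts, harmonic):
    """Per-pixel loop over bins: the definitional (uncorrected) transform."""
    rows, cols, K = counts.shape
    G = np.zeros((rows, cols))
    S = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            tot = counts[r, c].sum()
            if tot == 0:
                continue
            g = s = 0.0
            for k in range(K):
                g += counts[r, c, k] * np.cos(2 * np.pi * harmonic * k / K)
                s += counts[r, c, k] * np.sin(2 * np.pi * harmonic * k / K)
            G[r, c] = g / tot
            S[r, c] = s / tot
    return G, S


class TestClosedForm:
    def test_zero_lifetime_is_unit_point(self):
        assert pp.single_exp_phasor(0.0, RATE, 1) == (1.0, 0.0)

    def test_apex_at_n_omega_tau_one(self):
        tau = 1.0 / OMEGA
        g, s = pp.single_exp_phasor(tau, RATE, 1)
        assert abs(g - 0.5) < 1e-14 and abs(s - 0.5) < 1e-14

    def test_against_dense_fourier_integral(self):
        # oracle: numerical Fourier integral of the continuous exponential
        tau = 3.1
        t = np.linspace(0, 300 * tau, 3_000_001)
        decay = np.exp(-t / tau)
        G_num = np.trapezoid(decay * np.cos(OMEGA * t), t) / np.trapezoid(decay, t)
        S_num = np.trapezoid(decay * np.sin(OMEGA * t), t) / np.trapezoid(decay, t)
        g, s = pp.single_exp_phasor(tau, RATE, 1)
        assert abs(g - G_num) < 1e-7 and abs(s - S_num) < 1e-7
        # the value itself (to the printed 4-decimal precision)
        assert abs(g - 0.2917) < 1e-4
        assert abs(s - 0.4546) < 1e-4

    def test_negative_tau_raises(self):
        with pytest.raises(ValueError):
            pp.single_exp_phasor(-1.0, RATE, 1)

    def test_always_on_circle(self):
        for tau in np.geomspace(0.01, 50, 200):
            for n in (1, 2, 3):
                g, s = pp.single_exp_phasor(float(tau), RATE, n)
                assert abs(np.hypot(g - 0.5, s) - 0.5) < 1e-12


class TestTransform:
    def test_delta_in_bin_zero_uncorrected(self, ideal_acq):
        counts = np.zeros((1, 1, 256))
        counts[0, 0, 0] = 1000
        cube = pp.DecayCube(counts, RATE, ideal_acq.bin_width_ns)
        img = pp.phasor_transform(cube, harmonic=1, bin_correction=False)
        assert img.G[0, 0] == 1.0 and img.S[0, 0] == 0.0

    def test_uniform_counts_map_to_origin(self, ideal_acq):
        counts = np.full((1, 1, 256), 7.0)
        cube = pp.DecayCube(counts, RATE, ideal_acq.bin_width_ns)
        img = pp.phasor_transform(cube, harmonic=2, bin_correction=False)
        assert abs(img.G[0, 0]) < 1e-12 and abs(img.S[0, 0]) < 1e-12

    def test_equals_bruteforce_summation(self, ideal_acq, rng):
        for _ in range(10):
            counts = rng.integers(0, 50, size=(8, 8, 32)).astype(float)
            cube = pp.DecayCube(counts, RATE, ideal_acq.period_ns / 32)
            img = pp.phasor_transform(cube, harmonic=3, bin_correction=False)
            G, S = brute_force_phasor(counts, 3)
            np.testing.assert_allclose(img.G, G, rtol=0, atol=1e-12)
            np.testing.assert_allclose(img.S, S, rtol=0, atol=1e-12)

    def test_zero_intensity_pixels_masked(self, ideal_acq):
        counts = np.zeros((2, 1, 256))
        counts[0, 0, 3] = 5
        cube = pp.DecayCube(counts, RATE, ideal_acq.bin_width_ns)
        img = pp.phasor_transform(cube, harmonic=1)
        assert img.mask[0, 0] and not img.mask[1, 0]
        assert np.isfinite(img.G).all()

    def test_aliasing_harmonic_rejected(self, ideal_acq):
        counts = np.ones((1, 1, 16))
        cube = pp.DecayCube(counts, RATE, ideal_acq.period_ns / 16)
        with pytest.raises(ValueError, match="alias"):
            pp.phasor_transform(cube, harmonic=8)

    def test_bin_corrected_profiles_on_circle(self, ideal_acq):
        # noise-free single-exponential bin-integrated profiles, K = 256,
        # harmonics 1 and 2, tau in [0.1, 10]: distance to (0.5, 0) is 0.5
        # to machine precision
        for n in (1, 2):
            for tau in np.geomspace(0.1, 10, 25):
                cube = noise_free_cube([(float(tau), 1.0)], ideal_acq)
                img = pp.phasor_transform(cube, harmonic=n)
                dev = np.hypot(img.G[0, 0] - 0.5, img.S[0, 0]) - 0.5
                assert abs(dev) < 1e-9

    def test_bin_corrected_profile_near_closed_form(self, ideal_acq):
        # residual is the tangential discretisation bias, O((n/K)^2)
        cube = noise_free_cube([(2.0, 1.0)], ideal_acq)
        img = pp.phasor_transform(cube, harmonic=2)
        g0, s0 = pp.single_exp_phasor(2.0, RATE, 2)
        assert np.hypot(img.G[0, 0] - g0, img.S[0, 0] - s0) < 2e-4
        tau = pp.phase_lifetime(img.G[0, 0], img.S[0, 0], RATE, 2)
        assert abs(tau / 2.0 - 1) < 1e-3

    def test_correction_factor_value(self):
        theta = 2 * np.pi * 2 / 256
        z = bin_correction_factor(2, 256)
        assert abs(z - np.exp(1j * theta / 2) * np.cos(theta / 2)) < 1e-15


class TestLinearMixing:
    def test_sum_of_histograms_is_photon_weighted_average(self, ideal_acq):
        p1 = pp.decay_profile([(1.1, 1.0)], ideal_acq) * 3e4
        p2 = pp.decay_profile([(3.1, 1.0)], ideal_acq) * 1e4

        def phasor_of(hist):
            cube = pp.DecayCube(
                hist[None, None, :], RATE, ideal_acq.bin_width_ns
            )
            img = pp.phasor_transform(cube, harmonic=2)
            return img.G[0, 0] + 1j * img.S[0, 0]

        z1, z2, zmix = phasor_of(p1), phasor_of(p2), phasor_of(p1 + p2)
        w1 = p1.sum() / (p1.sum() + p2.sum())
        assert abs(zmix - (w1 * z1 + (1 - w1) * z2)) < 1e-12

    def test_mixture_lies_on_chord(self, ideal_acq):
        # fraction recovered from the position along the chord
        taus = (1.6, 2.2)
        f = 0.35
        p1 = pp.decay_profile([(taus[0], 1.0)], ideal_acq) * f
        p2 = pp.decay_profile([(taus[1], 1.0)], ideal_acq) * (1 - f)
        cube = pp.DecayCube((p1 + p2)[None, None, :], RATE, ideal_acq.bin_width_ns)
        img = pp.phasor_transform(cube, harmonic=2)
        z = img.G[0, 0] + 1j * img.S[0, 0]

        def endpoint(prof):
            c = pp.DecayCube(prof[None, None, :], RATE, ideal_acq.bin_width_ns)
            i = pp.phasor_transform(c, harmonic=2)
            return i.G[0, 0] + 1j * i.S[0, 0]

        z1, z2 = endpoint(p1), endpoint(p2)
        # photon-weighted position on the chord
        assert abs(z - (f * z1 + (1 - f) * z2)) < 1e-12


class TestCalibration:
    def test_identity_reference_is_noop(self, ideal_acq):
        cube = noise_free_cube([(2.0, 1.0)], ideal_acq, scale=1e4)
        img = pp.phasor_transform(cube, harmonic=2)
        ref = pp.CalibrationRef.identity(3.1, RATE, 2)
        # identity maps theoretical onto itself; correction is exactly 1
        assert abs(ref.correction - 1.0) < 1e-14
        out = pp.calibrate(img, ref)
        np.testing.assert_allclose(out.G, img.G, atol=1e-14)
        np.testing.assert_allclose(out.S, img.S, atol=1e-14)
        assert out.calibrated and not img.calibrated

    def test_rotated_reference_rotates_back(self):
        g0, s0 = pp.single_exp_phasor(3.1, RATE, 2)
        rot = np.exp(1j * np.deg2rad(10))
        meas = (g0 + 1j * s0) * rot
        ref = pp.CalibrationRef(3.1, (meas.real, meas.imag), RATE, 2)
        assert abs(ref.phase_offset + np.deg2rad(10)) < 1e-12
        assert abs(ref.modulation_factor - 1.0) < 1e-12
        img = pp.PhasorImage(
            G=np.array([[meas.real]]),
            S=np.array([[meas.imag]]),
            intensity=np.array([[100.0]]),
            harmonic=2,
            repetition_rate=RATE,
        )
        out = pp.calibrate(img, ref)
        assert abs(out.G[0, 0] - g0) < 1e-12
        assert abs(out.S[0, 0] - s0) < 1e-12

    def test_origin_reference_rejected(self):
        with pytest.raises(ValueError, match="origin|modulation"):
            pp.CalibrationRef(3.1, (0.0, 0.0), RATE, 2)

    def test_harmonic_mismatch_rejected(self, ideal_acq):
        cube = noise_free_cube([(2.0, 1.0)], ideal_acq)
        img = pp.phasor_transform(cube, harmonic=2)
        ref = pp.CalibrationRef.identity(3.1, RATE, 1)
        with pytest.raises(ValueError, match="harmonic"):
            pp.calibrate(img, ref)

    def test_double_calibration_rejected(self, ideal_acq):
        cube = noise_free_cube([(2.0, 1.0)], ideal_acq)
        img = pp.phasor_transform(cube, harmonic=2)
        ref = pp.CalibrationRef.identity(3.1, RATE, 2)
        out = pp.calibrate(img, ref)
        with pytest.raises(ValueError, match="calibrated"):
            pp.calibrate(out, ref)

    def test_shifted_irf_calibrates_back_onto_circle(self):
        # cube with the IRF peak at 1 ns, calibrated against a 3.1 ns
        # reference simulated identically: pure pixels return to the circle
        acq = pp.AcquisitionSpec(irf_center=1.0, irf_sigma=0.15, seed=21)
        sp = pp.SpeciesSpec(name="X", components=[(2.0, 1.0)], brightness=1e3)
        cube = pp.simulate_uniform_cube(sp, acq, shape=(32, 32))
        ref_sp = pp.SpeciesSpec(name="R", components=[(3.1, 1.0)], brightness=1e3)
        ref_cube = pp.simulate_uniform_cube(
            ref_sp, acq.model_copy(update={"seed": 22}), shape=(32, 32)
        )
        ref = pp.CalibrationRef.from_image(
            pp.phasor_transform(ref_cube, harmonic=2), 3.1
        )
        img = pp.calibrate(pp.phasor_transform(cube, harmonic=2), ref)
        w = img.intensity[img.mask]
        cg = np.average(img.G[img.mask], weights=w)
        cs = np.average(img.S[img.mask], weights=w)
        # before calibration the cluster sits far off the circle
        raw = pp.phasor_transform(cube, harmonic=2)
        raw_dev = abs(np.hypot(raw.G[img.mask].mean() - 0.5, raw.S[img.mask].mean()) - 0.5)
        dev = abs(np.hypot(cg - 0.5, cs) - 0.5)
        # shot-noise SE of the weighted centroid plus the discretisation remap
        se = np.hypot(img.G[img.mask].std(), img.S[img.mask].std()) / np.sqrt(img.mask.sum())
        assert raw_dev > 0.01
        assert dev < 3 * se + 5e-4


class TestLifetimes:
    def test_apex_lifetime_identity(self):
        tau_p = pp.phase_lifetime(0.5, 0.5, RATE, 1)
        tau_m = pp.modulation_lifetime(0.5, 0.5, RATE, 1)
        assert abs(tau_p - 1.0 / OMEGA) < 1e-12
        assert abs(tau_m - 1.0 / OMEGA) < 1e-12
        assert abs(tau_p - 1.989) < 1e-3

    def test_unit_point_zero_lifetime(self):
        assert pp.phase_lifetime(1.0, 0.0, RATE, 1) == 0.0
        assert pp.modulation_lifetime(1.0, 0.0, RATE, 1) == 0.0

    def test_invalid_regions_flagged_nan(self):
        assert np.isnan(pp.phase_lifetime(0.0, 0.5, RATE, 1))
        assert np.isnan(pp.phase_lifetime(-0.1, 0.5, RATE, 1))
        assert np.isnan(pp.modulation_lifetime(0.9, 0.9, RATE, 1))

    def test_phase_equals_modulation_on_circle(self):
        for tau in (0.5, 1.1, 2.0, 3.1, 8.0):
            g, s = pp.single_exp_phasor(tau, RATE, 2)
            assert abs(pp.phase_lifetime(g, s, RATE, 2) - tau) < 1e-12
            assert abs(pp.modulation_lifetime(g, s, RATE, 2) - tau) < 1e-9

    def test_lifetime_monotone_along_semicircle(self):
        # short lifetimes near (1, 0), long near the origin
        phis = np.linspace(0.01, np.pi - 0.01, 100)
        g = 0.5 + 0.5 * np.cos(phis)
        s = 0.5 * np.sin(phis)
        taus = pp.phase_lifetime(g, s, RATE, 1)
        assert np.all(np.diff(taus) > 0)

    def test_recovers_simulated_1p1ns_within_2_percent(self):
        acq = pp.AcquisitionSpec(seed=31)
        sp = pp.SpeciesSpec(name="PLA", components=[(1.1, 1.0)], brightness=1e4)
        cube = pp.simulate_uniform_cube(sp, acq, shape=(32, 32))
        ref_sp = pp.SpeciesSpec(name="R", components=[(3.1, 1.0)], brightness=1e4)
        ref_cube = pp.simulate_uniform_cube(
            ref_sp, acq.model_copy(update={"seed": 32}), shape=(32, 32)
        )
        ref = pp.CalibrationRef.from_image(
            pp.phasor_transform(ref_cube, harmonic=2), 3.1
        )
        img = pp.calibrate(pp.phasor_transform(cube, harmonic=2), ref)
        w = img.intensity[img.mask]
        tau = pp.phase_lifetime(
            np.average(img.G[img.mask], weights=w),
            np.average(img.S[img.mask], weights=w),
            RATE,
            2,
        )
        assert abs(tau / 1.1 - 1) < 0.02


class TestPhasorIO:
    def test_tiff_sidecar_roundtrip(self, tmp_path, ideal_acq, rng):
        from phasorprint.io import load_phasor, save_phasor

        counts = rng.integers(0, 200, size=(8, 8, 256)).astype(float)
        cube = pp.DecayCube(counts, RATE, ideal_acq.bin_width_ns)
        img = pp.phasor_transform(cube, harmonic=2)
        p = tmp_path / "phasor.tif"
        save_phasor(img, p)
        back = load_phasor(p)
        np.testing.assert_allclose(back.G, img.G, atol=1e-6)
        np.testing.assert_allclose(back.S, img.S, atol=1e-6)
        assert back.harmonic == 2 and not back.calibrated
        assert np.array_equal(back.mask, img.mask)

    def test_density_histogram_counts_all_valid_pixels(self, ideal_acq, rng):
        from phasorprint.io import phasor_density

        prof = pp.decay_profile([(2.0, 1.0)], ideal_acq)
        counts = rng.poisson(500 * prof, size=(16, 16, 256)).astype(float)
        cube = pp.DecayCube(counts, RATE, ideal_acq.bin_width_ns)
        img = pp.phasor_transform(cube, harmonic=1)
        df = phasor_density(img, bins=64)
        assert df["count"].sum() == int(img.mask.sum())
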