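"""Pulse binning, scan averaging, chi-squared alignment and absorbance."""

import numpy as np
import pytest

from qclspec.instrument import ScanRecord, sample_absorbance, simulate_measurement
from qclspec.processing import (
    Spectrum,
    align_scan,
    average_scans,
    bin_pulses,
    characterise_rsd,
    compute_absorbance,
    process_measurement,
)


def _scan(intensities, wavenumbers=None):
    n = len(intensities)
    if wavenumbers is None:
        wavenumbers = np.linspace(1200.0, 925.0, n)
    return ScanRecord(
        pulse_intensities=np.asarray(intensities, dtype=float),
        wavenumber_per_pulse=np.asarray(wavenumbers, dtype=float),
    )


def _spectrum(values, lo=1000.0, hi=1100.0, **meta):
    n = len(values)
    return Spectrum(np.linspace(lo, hi, n), np.asarray(values, float), dict(meta))


class TestBinPulses:
    def test_constant_train_preserved(self):
        s = bin_pulses(_scan(np.full(1000, 3.5)), bin_size=10, n_points=100)
        np.testing.assert_allclose(s.values, 3.5)
        assert s.n_points == 100

    def test_default_binning_gives_390_points_at_07_spacing(
        self, default_instrument
    ):
        m = simulate_measurement({}, default_instrument.with_noise_disabled(), 1)
        s = bin_pulses(m.sample[0])
        assert s.n_points == 390
        spacing = np.mean(np.diff(s.wavenumbers))
        assert spacing == pytest.approx(0.705, abs=0.01)
        assert s.wavenumbers[0] > 925.0 and s.wavenumbers[-1] < 1200.0
        assert np.all(np.diff(s.wavenumbers) > 0)

    def test_bin_noise_reduction_sqrt_255(self):
        rng = np.random.default_rng(0)
        sigma = 0.02
        raw = 1.0 + rng.normal(0.0, sigma, 255 * 300)
        s = bin_pulses(_scan(raw), bin_size=255, n_points=300)
        observed = np.std(s.values, ddof=1)
        assert abs(observed - sigma / np.sqrt(255)) / (sigma / np.sqrt(255)) < 0.15

    def test_short_scan_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            bin_pulses(_scan(np.ones(100)), bin_size=255)
        with pytest.raises(ValueError, match="complete bins"):
            bin_pulses(_scan(np.ones(1000)), bin_size=10, n_points=200)


class TestAverageScans:
    def test_identical_spectra_idempotent(self):
        s = _spectrum(np.arange(50.0))
        avg = average_scans([s] * 10)
        np.testing.assert_array_equal(avg.values, s.values)
        assert avg.metadata["n_averaged"] == 10

    def test_noise_reduction_sqrt_10(self):
        rng = np.random.default_rng(1)
        sigma = 0.1
        base = np.zeros(4000)
        avg = average_scans(
            [_spectrum(base + rng.normal(0, sigma, 4000)) for _ in range(10)]
        )
        observed = np.std(avg.values, ddof=1)
        assert abs(observed - sigma / np.sqrt(10)) / (sigma / np.sqrt(10)) < 0.1

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_scans([])
        with pytest.raises(ValueError, match="grid"):
            average_scans([_spectrum(np.ones(10)), _spectrum(np.ones(11))])


class TestAlignScan:
    def _smooth(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 4 * np.pi, n)
        return np.sin(x) + 0.3 * np.cos(3 * x) + rng.normal(0, 0.001, n)

    def test_identity(self):
        ref = _spectrum(self._smooth())
        sol, aligned = align_scan(ref, ref)
        assert sol.bin_shift == 0
        assert sol.intensity_offset == pytest.approx(0.0, abs=1e-12)
        assert sol.chi_squared == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_array_equal(aligned.values, ref.values)

    @pytest.mark.parametrize("shift", [-3, -1, 1, 2, 3])
    def test_recovers_injected_shift_exactly(self, shift):
        base = self._smooth(300)
        ref = _spectrum(base)
        # target content displaced by `shift` bins: target[i] = ref[i + shift]
        target_vals = np.roll(base, -shift)
        target = _spectrum(target_vals)
        sol, aligned = align_scan(ref, target, max_shift=5)
        assert sol.bin_shift == shift
        interior = slice(5, 295)
        np.testing.assert_allclose(
            aligned.values[interior], ref.values[interior], atol=1e-12
        )

    @pytest.mark.parametrize("offset", [0.01, -0.01])
    def test_recovers_additive_offset(self, offset):
        ref = _spectrum(self._smooth())
        target = _spectrum(ref.values - offset)
        sol, aligned = align_scan(ref, target)
        assert sol.bin_shift == 0
        assert sol.intensity_offset == pytest.approx(offset, abs=1e-12)
        np.testing.assert_allclose(aligned.values, ref.values, atol=1e-12)

    def test_combined_shift_and_offset(self):
        base = self._smooth(300)
        ref = _spectrum(base)
        target = _spectrum(np.roll(base, -2) - 0.005)
        sol, _ = align_scan(ref, target, max_shift=5)
        assert sol.bin_shift == 2
        assert sol.intensity_offset == pytest.approx(0.005, abs=1e-10)

    def test_tie_broken_toward_smaller_shift(self):
        ref = _spectrum(np.ones(50))
        sol, _ = align_scan(ref, ref, max_shift=5)
        assert sol.bin_shift == 0

    def test_offset_disabled_mode(self):
        ref = _spectrum(self._smooth())
        target = _spectrum(ref.values - 0.01)
        sol, _ = align_scan(ref, target, fit_offset=False)
        assert sol.intensity_offset == 0.0

    def test_short_overlap_rejected(self):
        ref = _spectrum(np.ones(12))
        with pytest.raises(ValueError, match="overlap"):
            align_scan(ref, ref, max_shift=5)


class TestComputeAbsorbance:
    def test_blank_and_decade(self):
        bg = _spectrum(np.full(20, 0.8))
        np.testing.assert_allclose(compute_absorbance(bg, bg).values, 0.0)
        sample = _spectrum(np.full(20, 0.008))
        np.testing.assert_allclose(
            compute_absorbance(sample, bg).values, 2.0, atol=1e-12
        )

    def test_nonpositive_intensity_names_wavenumber(self):
        bg = _spectrum(np.ones(20))
        vals = np.ones(20)
        vals[7] = 0.0
        bad = Spectrum(bg.wavenumbers, vals)
        bad.values[7] = 0.0
        with pytest.raises(ValueError) as err:
            compute_absorbance(bad, bg)
        assert f"{bg.wavenumbers[7]:.2f}" in str(err.value)


class TestCharacteriseRSD:
    def test_identical_replicates_zero(self):
        reps = [_spectrum(np.full(30, 2.0)) for _ in range(5)]
        assert characterise_rsd(reps, (1000.0, 1100.0)) == 0.0

    def test_two_replicate_hand_value(self):
        # values {1, 3}: sample sd sqrt(2), mean 2 -> RSD = sqrt(2)/2
        reps = [_spectrum([1.0, 1.0]), _spectrum([3.0, 3.0])]
        assert characterise_rsd(reps, (1000.0, 1100.0)) == pytest.approx(
            np.sqrt(2) / 2
        )

    def test_window_outside_grid_rejected(self):
        reps = [_spectrum(np.ones(10)) for _ in range(3)]
        with pytest.raises(ValueError, match="window"):
            characterise_rsd(reps, (2000.0, 2100.0))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicate"):
            characterise_rsd([_spectrum(np.ones(10))], (1000.0, 1100.0))


class TestFullChain:
    def test_noiseless_chain_reproduces_injected_absorbance(
        self, default_instrument
    ):
        """bin -> align -> average -> ratio recovers sum(eps c L) exactly up
        to the sub-bin discretisation of the 0.7 cm-1 grid."""
        cfg = default_instrument.with_noise_disabled()
        conc = {"glucose": 400.0, "lactate": 60.0}
        m = simulate_measurement(conc, cfg, n_scans=3, seed=0)
        A = process_measurement(m)
        expected = sample_absorbance(conc, A.wavenumbers, cfg)
        assert np.max(np.abs(A.values - expected)) < 1e-5

    def test_chain_recovers_shifted_scans(self, default_instrument):
        """Integer-bin tuning jitter is removed by alignment up to one global
        calibration shift: the first scan's own jitter has no in-pipeline
        reference, so recovery is exact modulo a whole-spectrum bin shift."""
        from dataclasses import replace

        cfg = replace(
            default_instrument.with_noise_disabled(), scan_shift_sd=1.5
        )
        conc = {"glucose": 400.0}
        m = simulate_measurement(conc, cfg, n_scans=6, seed=5)
        A = process_measurement(m)
        spacing = np.mean(np.diff(A.wavenumbers))
        residuals = []
        for k in range(-5, 6):
            expected = sample_absorbance(conc, A.wavenumbers + k * spacing, cfg)
            residuals.append(np.max(np.abs(A.values - expected)))
        assert min(residuals) < 1e-4

    def test_default_noise_absorbance_floor(self, default_instrument):
        """At calibrated noise the absorbance residual is a few 1e-4 AU."""
        conc = {"glucose": 400.0}
        m = simulate_measurement(conc, default_instrument, n_scans=10, seed=5)
        A = process_measurement(m)
        expected = sample_absorbance(
            conc, A.wavenumbers, default_instrument.with_noise_disabled()
        )
        resid = A.values - expected
        window = (A.wavenumbers > 1000) & (A.wavenumbers < 1200)
        assert np.sqrt(np.mean(resid[window] ** 2)) < 2e-3
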