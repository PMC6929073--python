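"""Synthetic pulsed-QCL spectrometer: raw pulse-resolved scan generation.

Emulates a broadly tuneable external-cavity quantum cascade laser swept
1200 -> 925 cm-1 in 1 s (100 kHz repetition rate, 500 ns pulses, 5% duty
cycle) through either a transmission cell (165 um fiber gap) or an ATR
prism, onto a detector.  A scan is a sequence of per-pulse intensities with
a nominal wavenumber per pulse.

The statistical structure reproduced here is what the downstream processing
chain assumes:

* multiplicative pulse-to-pulse intensity noise (the dominant laser noise),
* a multiplicative scan-to-scan intensity offset drawn once per scan,
* an integer spectral-bin jitter of the wavenumber axis per scan (tuning
  start jitter; removed later by chi-squared alignment),
* an optional sub-bin axis offset shared by a whole measurement series
  (wavelength-calibration drift between series; *not* removable by
  integer-bin alignment),
* an optional per-series effective-pathlength scale factor (the fiber gap
  is re-assembled and the prism re-contacted between series, so the true
  optical pathlength varies slightly),
* an optional smooth per-series absorbance baseline applied to the sample
  measurements only (sample-vs-background drift with a series-correlated
  component, e.g. residue building up on the sensing surface during a
  series); because an unseen series carries an unseen baseline shape, this
  is the term that makes leave-one-series-out validation genuinely harder
  than leave-one-out,
* additive detector noise.

The series-level terms default to zero: the baseline study conditions are
per-pulse noise, scan offsets and axis jitter only.

Sample absorption follows Beer-Lambert: A(v) = sum_a eps_a(v) c_a L(v) on
top of a water background whose absorbance rises steeply below 970 cm-1.
The pathlength L is the fiber gap in transmission and the wavenumber-
dependent evanescent interaction length (reflections x sampling depth) in
ATR, which is what makes the ATR analyte signal roughly seven times weaker.

The band library is synthetic: band positions for lactate (1040, 1124 cm-1)
and urea (~1160 cm-1) follow their known mid-IR bands; glucose bands at
1036/1080/1110/1152 cm-1 and a broad albumin profile are taken from standard
solution-phase mid-IR literature positions, with amplitudes calibrated so a
full-range glucose sample at 165 um gives ~0.1 AU peak absorbance.  It is a
plausible stand-in for the real absorptivities, not a fit to any measured
spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .optics import PrismGeometry, sampling_profile

__all__ = [
    "AnalyteBand",
    "BAND_LIBRARY",
    "InstrumentConfig",
    "ScanRecord",
    "Measurement",
    "emission_envelope",
    "water_absorbance_per_um",
    "sample_absorbance",
    "sample_transmittance",
    "simulate_measurement",
]


@dataclass(frozen=True)
class AnalyteBand:
    """Gaussian absorption band: absorbance per (mg/dL) per um pathlength."""

    center: float  # cm-1
    width_fwhm: float  # cm-1
    peak_absorptivity: float  # AU * dL / (mg * um)

    def __post_init__(self) -> None:
        if self.width_fwhm <= 0:
            raise ValueError("band width must be positive")
        if self.peak_absorptivity < 0:
            raise ValueError("peak absorptivity must be non-negative")


#: Synthetic analyte band library (see module docstring).
BAND_LIBRARY: dict[str, tuple[AnalyteBand, ...]] = {
    "glucose": (
        AnalyteBand(1036.0, 35.0, 6.0e-7),
        AnalyteBand(1080.0, 35.0, 7.0e-7),
        AnalyteBand(1110.0, 35.0, 5.0e-7),
        AnalyteBand(1152.0, 35.0, 3.5e-7),
    ),
    "albumin": (
        AnalyteBand(1075.0, 100.0, 1.0e-7),
        AnalyteBand(1160.0, 60.0, 0.6e-7),
    ),
    "urea": (
        AnalyteBand(1160.0, 35.0, 8.0e-7),
    ),
    "lactate": (
        AnalyteBand(1040.0, 40.0, 1.6e-6),
        AnalyteBand(1124.0, 40.0, 1.2e-6),
    ),
}


@dataclass(frozen=True)
class InstrumentConfig:
    """Pulse timing, scan parameters, noise levels and the sensing geometry.

    Times in ns/kHz/s, wavenumbers in cm-1, pathlengths in um; noise
    magnitudes are fractions of the local intensity except
    ``scan_shift_sd``/``series_shift_sd`` which are in spectral bins
    (one bin = ``pulses_per_bin`` pulses).
    """

    pulse_width: float = 500.0  # ns
    repetition_rate: float = 100.0  # kHz
    scan_range: tuple[float, float] = (1200.0, 925.0)  # cm-1, (start, stop)
    tuning_speed: float = 275.0  # cm-1 / s
    per_pulse_rsd: float = 0.0354
    scan_offset_sd: float = 0.001
    scan_shift_sd: float = 1.0  # spectral bins, integer jitter per scan
    series_shift_sd: float = 0.0  # spectral bins, sub-bin offset per series
    series_pathlength_sd: float = 0.0  # fractional pathlength change per series
    series_baseline_sd: float = 0.0  # AU, smooth per-series sample-drift baseline
    detector_noise_sd: float = 5.0e-4  # additive, units of peak envelope
    setup_type: str = "transmission"  # or "atr"
    transmission_path: float = 165.0  # um
    prism: PrismGeometry = field(default_factory=PrismGeometry)
    effective_depth_factor: float = 2.6
    pulses_per_bin: int = 255
    band_library: tuple[tuple[str, tuple[AnalyteBand, ...]], ...] = tuple(
        sorted(BAND_LIBRARY.items())
    )

    def __post_init__(self) -> None:
        if self.setup_type not in ("transmission", "atr"):
            raise ValueError("setup_type must be 'transmission' or 'atr'")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError(f"duty cycle {self.duty_cycle:.3f} outside (0, 1]")
        if self.scan_range[0] <= self.scan_range[1]:
            raise ValueError("scan_range must be (high, low) in cm-1")
        if self.tuning_speed <= 0 or self.repetition_rate <= 0:
            raise ValueError("tuning_speed and repetition_rate must be positive")
        for sd in (self.per_pulse_rsd, self.scan_offset_sd, self.detector_noise_sd):
            if sd < 0:
                raise ValueError("noise magnitudes must be non-negative")

    @property
    def duty_cycle(self) -> float:
        return self.pulse_width * 1e-9 * self.repetition_rate * 1e3

    @property
    def scan_span(self) -> float:
        return self.scan_range[0] - self.scan_range[1]

    @property
    def scan_duration(self) -> float:
        """Seconds per scan."""
        return self.scan_span / self.tuning_speed

    @property
    def pulses_per_scan(self) -> int:
        return int(round(self.repetition_rate * 1e3 * self.scan_duration))

    @property
    def pulse_wavenumbers(self) -> np.ndarray:
        """Nominal wavenumber of each pulse, descending over the scan."""
        n = self.pulses_per_scan
        step = self.scan_span / n
        return self.scan_range[0] - step * (np.arange(n) + 0.5)

    @property
    def bands(self) -> dict[str, tuple[AnalyteBand, ...]]:
        return dict(self.band_library)

    def with_noise_disabled(self) -> "InstrumentConfig":
        return replace(
            self,
            per_pulse_rsd=0.0,
            scan_offset_sd=0.0,
            scan_shift_sd=0.0,
            series_shift_sd=0.0,
            series_pathlength_sd=0.0,
            detector_noise_sd=0.0,
        )

    def pathlength(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Sample pathlength in um: fixed gap or evanescent interaction length."""
        wavenumbers = np.asarray(wavenumbers, dtype=float)
        if self.setup_type == "transmission":
            return np.full_like(wavenumbers, self.transmission_path)
        return sampling_profile(
            self.prism, wavenumbers, self.effective_depth_factor
        )


@dataclass
class ScanRecord:
    """One laser sweep: per-pulse detector intensities with a nominal axis."""

    pulse_intensities: np.ndarray
    wavenumber_per_pulse: np.ndarray  # descending, nominal
    series_id: int = 0
    day_id: int = 0
    sample_id: int = 0
    is_background: bool = False


@dataclass
class Measurement:
    """A background measurement and a sample measurement (n scans each)."""

    background: list[ScanRecord]
    sample: list[ScanRecord]
    concentrations: dict[str, float]
    series_id: int = 0
    day_id: int = 0
    sample_id: int = 0


_ENVELOPE_CENTER = 1080.0
_ENVELOPE_WIDTH = 350.0


def _envelope_raw(wavenumber: np.ndarray) -> np.ndarray:
    """Smooth laser gain profile, peak 1 at the envelope centre; valid anywhere."""
    return np.exp(-(((np.asarray(wavenumber, float) - _ENVELOPE_CENTER) / _ENVELOPE_WIDTH) ** 2))


def emission_envelope(
    wavenumber, scan_range: tuple[float, float] = (1200.0, 925.0)
):
    """Relative laser emission intensity over the scan range (max 1)."""
    wn = np.asarray(wavenumber, dtype=float)
    hi, lo = scan_range
    if np.any(wn > hi + 1e-9) or np.any(wn < lo - 1e-9):
        raise ValueError(f"wavenumber outside the scan range {lo}-{hi} cm-1")
    out = _envelope_raw(wn)
    return float(out) if np.isscalar(wavenumber) else out


def water_absorbance_per_um(wavenumber) -> np.ndarray:
    """Water background absorbance per um pathlength.

    Flat weak absorption across the fingerprint region plus a logistic rise
    below ~970 cm-1 (libration-band flank), which is what amplifies noise at
    the low-wavenumber end of transmission measurements.
    """
    wn = np.asarray(wavenumber, dtype=float)
    return 0.004 + 0.008 / (1.0 + np.exp((wn - 970.0) / 12.0))


def _analyte_absorbance_per_um(
    concentrations: dict[str, float],
    wavenumbers: np.ndarray,
    bands: dict[str, tuple[AnalyteBand, ...]],
) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    A = np.zeros_like(wn)
    for name, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}")
        if c == 0:
            continue
        if name not in bands:
            raise KeyError(f"no bands defined for analyte {name!r}")
        for b in bands[name]:
            sigma = b.width_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            A += c * b.peak_absorptivity * np.exp(-0.5 * ((wn - b.center) / sigma) ** 2)
    return A


def sample_absorbance(
    concentrations: dict[str, float],
    wavenumber,
    config: InstrumentConfig,
    include_water: bool = False,
) -> np.ndarray:
    """Beer-Lambert absorbance sum(eps_a c_a) L (+ water if requested)."""
    wn = np.asarray(wavenumber, dtype=float)
    L = config.pathlength(wn)
    A = _analyte_absorbance_per_um(concentrations, wn, config.bands) * L
    if include_water:
        A = A + water_absorbance_per_um(wn) * L
    return A


def sample_transmittance(
    concentrations: dict[str, float], wavenumber, config: InstrumentConfig
):
    """Fraction of light transmitted: 10^-(analyte + water absorbance)."""
    A = sample_absorbance(concentrations, wavenumber, config, include_water=True)
    T = np.power(10.0, -A)
    return float(T) if np.isscalar(wavenumber) else T


def _clean_signal_extended(
    concentrations: dict[str, float],
    config: InstrumentConfig,
    pad_pulses: int,
    pathlength_scale: float = 1.0,
) -> np.ndarray:
    """Noise-free per-pulse intensity on an axis extended by pad_pulses each side.

    The extension lets a jittered scan be realised as a slice of one
    precomputed array instead of re-evaluating every band per scan.
    """
    n = config.pulses_per_scan
    step = config.scan_span / n
    idx = np.arange(-pad_pulses, n + pad_pulses)
    wn = config.scan_range[0] - step * (idx + 0.5)
    L = config.pathlength(wn) * pathlength_scale
    A = _analyte_absorbance_per_um(concentrations, wn, config.bands) * L
    A += water_absorbance_per_um(wn) * L
    return _envelope_raw(wn) * np.power(10.0, -A)


def make_baseline_profile(
    config: InstrumentConfig, rng: np.random.Generator, n_harmonics: int = 3
):
    """Draw a smooth random absorbance baseline profile b(wavenumber) in AU.

    A few low-order cosine harmonics over the scan span with total standard
    deviation ``series_baseline_sd``; returns a vectorised callable.
    """
    sd = config.series_baseline_sd
    hi, lo = config.scan_range
    amps = rng.normal(0.0, sd / math.sqrt(n_harmonics), n_harmonics)
    phases = rng.uniform(0.0, 2.0 * math.pi, n_harmonics)

    def profile(wn: np.ndarray) -> np.ndarray:
        x = (np.asarray(wn, dtype=float) - lo) / (hi - lo)
        out = np.zeros_like(x)
        for k in range(n_harmonics):
            out += math.sqrt(2.0) * amps[k] * np.cos((k + 1) * math.pi * x + phases[k])
        return out

    return profile


def _simulate_scans(
    clean_ext: np.ndarray,
    config: InstrumentConfig,
    n_scans: int,
    rng: np.random.Generator,
    pad_pulses: int,
    series_shift_bins: float,
    meta: dict,
) -> list[ScanRecord]:
    n = config.pulses_per_scan
    nominal = config.pulse_wavenumbers
    records = []
    for _ in range(n_scans):
        k_bins = 0
        if config.scan_shift_sd > 0:
            k_bins = int(round(rng.normal(0.0, config.scan_shift_sd)))
        shift = int(round((k_bins + series_shift_bins) * config.pulses_per_bin))
        shift = int(np.clip(shift, -pad_pulses, pad_pulses))
        base = clean_ext[pad_pulses + shift : pad_pulses + shift + n]
        intensity = base
        if config.scan_offset_sd > 0:
            intensity = intensity * (1.0 + rng.normal(0.0, config.scan_offset_sd))
        if config.per_pulse_rsd > 0:
            intensity = intensity * (1.0 + rng.normal(0.0, config.per_pulse_rsd, n))
        if config.detector_noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.detector_noise_sd, n)
        if intensity is base:
            intensity = base.copy()
        records.append(
            ScanRecord(
                pulse_intensities=intensity,
                wavenumber_per_pulse=nominal,
                **meta,
            )
        )
    return records


def simulate_measurement(
    concentrations: dict[str, float],
    config: InstrumentConfig,
    n_scans: int = 10,
    series_id: int = 0,
    day_id: int = 0,
    sample_id: int = 0,
    seed: int | np.random.Generator | None = None,
    series_shift_bins: float = 0.0,
    pathlength_scale: float = 1.0,
    sample_drift_absorbance=None,
) -> Measurement:
    """Simulate one background (pure water) + one sample measurement.

    Each measurement is ``n_scans`` laser sweeps; the background records use
    zero analyte concentrations.  ``series_shift_bins`` is the sub-bin
    wavenumber-axis offset and ``pathlength_scale`` the effective-pathlength
    factor shared by the whole series (the caller draws them once per
    series).  Reproducible for a given seed or Generator.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    for name, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pad = max(
        int(math.ceil((6.0 * config.scan_shift_sd + abs(series_shift_bins) + 1.0)))
        * config.pulses_per_bin,
        config.pulses_per_bin,
    )
    meta = dict(series_id=series_id, day_id=day_id, sample_id=sample_id)
    bg_clean = _clean_signal_extended({}, config, pad, pathlength_scale)
    bg = _simulate_scans(
        bg_clean, config, n_scans, rng, pad, series_shift_bins,
        {**meta, "is_background": True},
    )
    sm_clean = _clean_signal_extended(concentrations, config, pad, pathlength_scale)
    if sample_drift_absorbance is not None:
        n = config.pulses_per_scan
        step = config.scan_span / n
        wn_ext = config.scan_range[0] - step * (np.arange(-pad, n + pad) + 0.5)
        sm_clean = sm_clean * np.power(10.0, -sample_drift_absorbance(wn_ext))
    sm = _simulate_scans(
        sm_clean, config, n_scans, rng, pad, series_shift_bins,
        {**meta, "is_background": False},
    )
    return Measurement(
        background=bg,
        sample=sm,
        concentrations=dict(concentrations),
        series_id=series_id,
        day_id=day_id,
        sample_id=sample_id,
    )
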