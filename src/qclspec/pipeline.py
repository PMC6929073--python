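"""End-to-end study orchestration: design -> simulate -> process -> quantify.

The default study mirrors the full in vitro experiment layout: one
A-optimal 25-sample concentration design measured in four series (two
series on each of two days) in both the ATR and the transmission
configuration, with a fresh water background before every sample
measurement.  Every stage is a pure function of (inputs, config, seed);
per-stage random streams are spawned from one root seed so the whole study
is reproducible bit-for-bit.

Outputs are plain-text artifacts: the design table and per-setup absorbance
matrices as CSV, cross-validation tables and the predicted-vs-reference
glucose scatter as JSON, plus a manifest recording configuration, seeds and
file paths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import PreprocessConfig, best_result, cross_validate
from .design import ConcentrationRanges, SampleDesign, a_optimal_design
from .instrument import InstrumentConfig, make_baseline_profile, simulate_measurement
from .processing import Spectrum, process_measurement

__all__ = ["StudyConfig", "StudyManifest", "run_study", "simulate_setup"]


@dataclass(frozen=True)
class StudyConfig:
    """Layout and stage parameters of a full two-setup study."""

    n_samples: int = 25
    n_series: int = 4
    series_days: tuple[int, ...] = (0, 0, 1, 1)
    n_scans: int = 10
    setups: tuple[str, ...] = ("transmission", "atr")
    schemes: tuple[str, ...] = ("loocv", "l5ocv", "ldocv")
    max_lv: int = 8
    candidate_grid_levels: int = 4
    design_restarts: int = 10
    bin_size: int = 255
    n_points: int = 390
    max_shift: int = 5
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    ranges: ConcentrationRanges = field(default_factory=ConcentrationRanges.default)

    def __post_init__(self) -> None:
        if len(self.series_days) != self.n_series:
            raise ValueError("series_days must list a day for every series")
        for s in self.setups:
            if s not in ("transmission", "atr"):
                raise ValueError(f"unknown setup {s!r}")

    def instrument_for(self, setup: str) -> InstrumentConfig:
        return replace(self.instrument, setup_type=setup)


@dataclass
class StudyManifest:
    seed: int
    version: str
    config: dict
    design_criterion: float
    n_sample_measurements: int
    n_background_measurements: int
    artifacts: dict[str, str] = field(default_factory=dict)


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def simulate_setup(
    design: SampleDesign,
    config: StudyConfig,
    setup: str,
    seed_seq: np.random.SeedSequence,
) -> list[Spectrum]:
    """Simulate and process all (sample x series) measurements of one setup."""
    inst = config.instrument_for(setup)
    rng = np.random.default_rng(seed_seq)
    spectra: list[Spectrum] = []
    for series in range(config.n_series):
        series_shift = (
            rng.normal(0.0, inst.series_shift_sd) if inst.series_shift_sd > 0 else 0.0
        )
        path_scale = 1.0
        if inst.series_pathlength_sd > 0:
            path_scale = 1.0 + rng.normal(0.0, inst.series_pathlength_sd)
        baseline = (
            make_baseline_profile(inst, rng) if inst.series_baseline_sd > 0 else None
        )
        day = config.series_days[series]
        for i in range(design.n_samples):
            meas = simulate_measurement(
                design.sample_concentrations(i),
                inst,
                n_scans=config.n_scans,
                series_id=series,
                day_id=day,
                sample_id=i,
                seed=rng,
                series_shift_bins=series_shift,
                pathlength_scale=path_scale,
                sample_drift_absorbance=baseline,
            )
            spectra.append(
                process_measurement(
                    meas, config.bin_size, config.n_points, config.max_shift
                )
            )
    return spectra


def _quantify(
    spectra: list[Spectrum],
    design: SampleDesign,
    config: StudyConfig,
) -> dict:
    X = np.vstack([s.values for s in spectra])
    sample_ids = np.array([s.metadata["sample_id"] for s in spectra])
    series_ids = np.array([s.metadata["series_id"] for s in spectra])
    Y = design.concentrations[sample_ids]
    names = design.analyte_names

    out: dict = {}
    for scheme in config.schemes:
        results = cross_validate(
            X,
            Y,
            sample_ids,
            series_ids,
            scheme,
            max_lv=config.max_lv,
            preprocess_config=config.preprocess,
            analyte_names=names,
        )
        table = {}
        for name in names:
            best = best_result(results, name)
            table[name] = {
                "rmsecv": best.rmsecv[name],
                "r2": best.r2[name],
                "n_lv": best.n_lv,
                "per_lv": [
                    {"n_lv": r.n_lv, "rmsecv": r.rmsecv[name], "r2": r.r2[name]}
                    for r in results
                ],
            }
        out[scheme] = table
        if scheme == "l5ocv" and "glucose" in names:
            j = names.index("glucose")
            best = best_result(results, "glucose")
            ref = best.reference[:, j]
            pred = best.predictions[:, j]
            slope, intercept = np.polyfit(ref, pred, 1)
            out["glucose_scatter"] = {
                "reference": ref.tolist(),
                "predicted": pred.tolist(),
                "n_lv": best.n_lv,
                "slope": float(slope),
                "intercept": float(intercept),
            }
    return out


def _config_dict(config: StudyConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return enc(config)


def run_study(
    config: StudyConfig | None = None,
    seed: int = 7,
    out_dir: str | Path | None = None,
) -> tuple[StudyManifest, dict]:
    """Run the complete study and return (manifest, results).

    Results hold, per setup, the cross-validation tables for every scheme
    (per-analyte RMSECV, R^2 and chosen latent-variable count) and the
    glucose predicted-vs-reference scatter for the leave-5-out scheme.
    When ``out_dir`` is given, design/spectra/results/manifest are written
    there as CSV/JSON.
    """
    config = config or StudyConfig()
    design_seq, *setup_seqs = _spawn_seeds(seed, 1 + len(config.setups))
    design = a_optimal_design(
        config.ranges,
        n_samples=config.n_samples,
        candidate_grid_levels=config.candidate_grid_levels,
        seed=design_seq.generate_state(1)[0] % (2**31),
        n_restarts=config.design_restarts,
    )

    results: dict = {}
    all_spectra: dict[str, list[Spectrum]] = {}
    for setup, seq in zip(config.setups, setup_seqs):
        spectra = simulate_setup(design, config, setup, seq)
        all_spectra[setup] = spectra
        results[setup] = _quantify(spectra, design, config)

    n_meas = config.n_samples * config.n_series * len(config.setups)
    manifest = StudyManifest(
        seed=seed,
        version=__version__,
        config=_config_dict(config),
        design_criterion=design.a_criterion,
        n_sample_measurements=n_meas,
        n_background_measurements=n_meas,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        design_path = out / "design.csv"
        design.to_frame().to_csv(design_path, index=False)
        manifest.artifacts["design"] = str(design_path)
        for setup, spectra in all_spectra.items():
            rows = []
            for s in spectra:
                rows.append(
                    {
                        "sample_id": s.metadata["sample_id"],
                        "series_id": s.metadata["series_id"],
                        "day_id": s.metadata["day_id"],
                        **{f"{w:.3f}": v for w, v in zip(s.wavenumbers, s.values)},
                    }
                )
            path = out / f"absorbance_{setup}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            manifest.artifacts[f"absorbance_{setup}"] = str(path)
        results_path = out / "results.json"
        results_path.write_text(json.dumps(results, indent=2, sort_keys=True))
        manifest.artifacts["results"] = str(results_path)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True, default=str)
        )
        manifest.artifacts["manifest"] = str(manifest_path)

    return manifest, results
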