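"""End-to-end screening runs: generate -> simulate -> decompose ->
calibrate -> OCR -> classify -> report.

Mirrors the instrument's software flow (sample, measure, sort) as pure
computation. A single run seed is expanded deterministically into
per-stage substreams, so identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import json

import numpy as np
import pandas as pd

from . import io as seedio
from .calibration import CalibrationModel, apply_calibration, fit_calibration
from .decomposition import oil_amplitude_single_echo, water_amplitude
from .screening import (
    ScreeningReport,
    classify,
    compute_ocr,
    empirical_error_rates,
    fit_class_gaussians,
    model_error_rates,
    separability,
)
from .signal_model import RelaxationParams
from .synthetic_data import (
    generate_population,
    load_preset,
    population_to_signals,
    reference_calibration,
    screening_acquisition,
)

__all__ = ["ConfigError", "RunConfig", "run_screening", "run_calibration", "measure_population"]


class ConfigError(ValueError):
    """A run configuration field is missing or invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end screening run.

    Exactly one calibration source: either ``standards_csv`` (a fit is
    performed) or the fixed pair ``(k_mg_per_v, b_mg)``.
    ``correct_oil_decay`` chooses between the explicitly TE-corrected oil
    amplitude and the raw-echo convention whose bias the calibration
    absorbs when standards are measured at the same TE.
    """

    preset: str = "maize_zd958"
    n_kernels: int = 1260
    seed: int = 0
    threshold_pct: float = 4.25
    te_ms: float = 7.5
    noise_sd_v: float = 0.0
    n_averages: int = 2
    correct_oil_decay: bool = True
    standards_csv: str | None = None
    k_mg_per_v: float | None = 361.7
    b_mg: float | None = 0.0
    # physical signal-per-mass constant of the simulated instrument, used to
    # turn generated masses into signal amplitudes (distinct from the applied
    # calibration above, which may deliberately carry the raw-echo bias)
    true_k_mg_per_v: float = 361.7
    true_b_mg: float = 0.0
    t2_oil_ms: float = 100.0
    t2_water_ms: float = 0.75
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.n_kernels < 1:
            raise ConfigError("n_kernels: must be >= 1")
        if self.threshold_pct <= 0:
            raise ConfigError("threshold_pct: must be > 0")
        if self.standards_csv is not None:
            # standards file is the single calibration source; drop the fixed pair
            object.__setattr__(self, "k_mg_per_v", None)
            object.__setattr__(self, "b_mg", None)
        elif self.k_mg_per_v is None or self.b_mg is None:
            raise ConfigError("calibration source: standards_csv or both k_mg_per_v and b_mg required")


def _substreams(seed: int, n: int) -> list[int]:
    """Expand one run seed into deterministic per-stage sub-seeds (< 2^31)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def _build_calibration(config: RunConfig) -> CalibrationModel:
    if config.standards_csv is not None:
        standards = seedio.read_standards_csv(config.standards_csv)
        return fit_calibration(standards["signal_v"], standards["mass_mg"])
    return reference_calibration(config.k_mg_per_v, config.b_mg)


def measure_population(
    records: pd.DataFrame,
    calib: CalibrationModel,
    relax: RelaxationParams,
    te_ms: float = 7.5,
    noise_sd_v: float = 0.0,
    n_averages: int = 2,
    seed: int | None = None,
    correct: bool = True,
    instrument_calib: CalibrationModel | None = None,
) -> pd.DataFrame:
    """Run the virtual measurement chain over a kernel population.

    ``instrument_calib`` is the physical signal-per-mass relation used to
    forward-simulate the echo trains; ``calib`` is the applied (possibly
    standards-fitted) calibration used to read masses back out. They
    coincide by default. Returns a copy of ``records`` with measured
    oil/water masses and OCR (columns ``oil_mass_mg``, ``water_mass_mg``,
    ``ocr_pct`` replaced by their measured values; the generator's truth
    is kept under ``true_ocr_pct`` / ``true_oil_mass_mg``).
    """
    acq = screening_acquisition(
        te_ms=te_ms, noise_sd_v=noise_sd_v, n_averages=n_averages, seed=seed
    )
    trains = population_to_signals(
        records, instrument_calib if instrument_calib is not None else calib, relax, acq
    )
    oil_sig = np.empty(len(trains))
    water_sig = np.empty(len(trains))
    for i, (_, train) in enumerate(trains):
        s_o = max(oil_amplitude_single_echo(train, te_ms, relax, correct=correct), 0.0)
        oil_sig[i] = s_o
        water_sig[i] = water_amplitude(train.fid_amplitude_v, s_o)
    out = records.copy()
    out["true_ocr_pct"] = records["ocr_pct"]
    out["true_oil_mass_mg"] = records["oil_mass_mg"]
    out["oil_mass_mg"] = apply_calibration(calib, oil_sig)
    out["water_mass_mg"] = apply_calibration(calib, water_sig)
    out["ocr_pct"] = compute_ocr(out["oil_mass_mg"].to_numpy(), out["mass_g"].to_numpy())
    return out


def run_screening(config: RunConfig) -> tuple[ScreeningReport, pd.DataFrame]:
    """Execute a full screening run; optionally write CSV/JSON/log outputs."""
    t0 = time.perf_counter()
    try:
        preset = load_preset(config.preset)
    except FileNotFoundError as exc:
        raise ConfigError(f"preset: {exc}") from exc
    if {"haploid", "diploid"} - set(preset.classes):
        raise ConfigError(
            f"preset: {preset.name!r} is not a two-class haploid/diploid population"
        )
    seed_pop, seed_sig = _substreams(config.seed, 2)
    log_lines = []

    pop = generate_population(preset, config.n_kernels, seed=seed_pop)
    log_lines.append(f"generate: {len(pop)} kernels from preset {preset.name}")

    calib = _build_calibration(config)
    log_lines.append(
        f"calibrate: k={calib.k_mg_per_v:.4g} mg/V b={calib.b_mg:.4g} mg "
        f"(r2={calib.r_squared:.6g}, n={calib.n_points})"
    )

    relax = RelaxationParams(config.t2_oil_ms, config.t2_water_ms)
    measured = measure_population(
        pop,
        calib,
        relax,
        te_ms=config.te_ms,
        noise_sd_v=config.noise_sd_v,
        n_averages=config.n_averages,
        seed=seed_sig,
        correct=config.correct_oil_decay,
        instrument_calib=reference_calibration(config.true_k_mg_per_v, config.true_b_mg),
    )
    log_lines.append(
        f"measure: {len(measured)} echo trains decomposed at TE={config.te_ms} ms "
        f"(correct_oil_decay={config.correct_oil_decay})"
    )

    measured["assigned_class"] = classify(measured["ocr_pct"].to_numpy(), config.threshold_pct)
    report = empirical_error_rates(measured, config.threshold_pct)
    class_model = fit_class_gaussians(measured)
    model_report = model_error_rates(class_model, config.threshold_pct)
    sep_ocr = separability(class_model, "ocr")
    sep_weight = (
        separability(class_model, "weight") if class_model.haploid_weight else None
    )
    log_lines.append(
        f"classify: threshold={config.threshold_pct}% "
        f"FN={report.false_negative_pct:.3g}% FP={report.false_positive_pct:.3g}%"
    )
    elapsed = time.perf_counter() - t0

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seedio.write_kernel_csv(measured, outdir / "kernels.csv")
        payload = {
            "config": {
                "preset": preset.name,
                "n_kernels": config.n_kernels,
                "seed": config.seed,
                "threshold_pct": config.threshold_pct,
                "te_ms": config.te_ms,
                "noise_sd_v": config.noise_sd_v,
                "n_averages": config.n_averages,
                "correct_oil_decay": config.correct_oil_decay,
            },
            "calibration": {"k_mg_per_v": calib.k_mg_per_v, "b_mg": calib.b_mg},
            "empirical": json.loads(report.to_json()),
            "model": json.loads(model_report.to_json()),
            "class_gaussians": {
                "haploid_ocr": [class_model.haploid_ocr.mean, class_model.haploid_ocr.sd],
                "diploid_ocr": [class_model.diploid_ocr.mean, class_model.diploid_ocr.sd],
            },
            "separability": {
                "ocr": sep_ocr.__dict__,
                "weight": sep_weight.__dict__ if sep_weight else None,
            },
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
        log_lines.append(f"write: kernels.csv, report.json ({elapsed:.2f} s)")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return report, measured


def run_calibration(standards_csv, out_json=None) -> CalibrationModel:
    """Fit the signal-to-mass line from a standards CSV; optionally write JSON."""
    standards = seedio.read_standards_csv(standards_csv)
    model = fit_calibration(standards["signal_v"], standards["mass_mg"])
    if out_json is not None:
        Path(out_json).write_text(model.to_json(), encoding="utf-8")
    return model
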