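"""Synthetic kernel populations and instrument event streams.

Everything downstream of the (out-of-scope) hardware is testable from
simulated inputs: labelled kernel populations drawn from per-class
Gaussians of OCR and weight, echo trains forward-simulated from each
kernel's oil/water masses by inverting the calibration line, feeder
success/failure event streams, and repeat measurements of a single
kernel under receiver noise.

Presets (shipped as JSON under ``seednmr/presets/``) encode observed
field populations: a maize induction cross with haploid OCR
N(3.6 %, 0.47) vs diploid N(5.5 %, 0.52) and weights N(0.40 g, 0.049) /
N(0.43 g, 0.035); two high-oil soybean cultivars, N(17.5 %, 2.0) and
N(20.4 %, 1.0); and a single reference kernel (0.42 g, mean OCR 6.7 %)
for stability runs. Within a class, OCR and weight are sampled
independently (no correlation structure is imposed), each truncated away
from non-physical values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, apply_calibration
from .decomposition import oil_amplitude_single_echo, water_amplitude
from .screening import compute_ocr
from .signal_model import (
    AcquisitionConfig,
    EchoTrain,
    KernelComposition,
    RelaxationParams,
    default_echo_grid,
    simulate_echo_train,
)

__all__ = [
    "ClassSpec",
    "PopulationPreset",
    "FeederModel",
    "FEEDER_PRESETS",
    "load_preset",
    "available_presets",
    "generate_population",
    "population_to_signals",
    "screening_acquisition",
    "reference_calibration",
    "simulate_feeder",
    "repeat_measurement",
]

#: Minimum physical kernel mass (g); the weight Gaussian is truncated here.
MIN_KERNEL_MASS_G = 0.05


@dataclass(frozen=True)
class ClassSpec:
    """Sampling Gaussians for one kernel class."""

    ocr_mean_pct: float
    ocr_sd_pct: float
    weight_mean_g: float
    weight_sd_g: float
    fraction: float


@dataclass(frozen=True)
class PopulationPreset:
    """A named population: per-class Gaussians plus a water-content model.

    ``wcr_mean_pct``/``wcr_sd_pct`` describe the water content ratio of
    dried kernels (moisture well below 15 %, present as bound water).
    """

    name: str
    classes: dict[str, ClassSpec]
    wcr_mean_pct: float = 10.0
    wcr_sd_pct: float = 1.0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("preset needs at least one class")
        total = sum(c.fraction for c in self.classes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for c in self.classes.values():
            if min(c.ocr_sd_pct, c.weight_sd_g, self.wcr_sd_pct) <= 0:
                raise ValueError("all sds must be positive")
            if not 0 < c.fraction <= 1:
                raise ValueError("fractions must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationPreset":
        classes = {k: ClassSpec(**v) for k, v in d["classes"].items()}
        return cls(
            name=d["name"],
            classes=classes,
            wcr_mean_pct=d.get("wcr_mean_pct", 10.0),
            wcr_sd_pct=d.get("wcr_sd_pct", 1.0),
        )


@dataclass(frozen=True)
class FeederModel:
    """Single-kernel pick-up success probability per seed-shape category."""

    success_probability: dict[str, float] = field(
        default_factory=lambda: dict(FEEDER_PRESETS)
    )

    def __post_init__(self) -> None:
        for cat, p in self.success_probability.items():
            if not 0 < p <= 1:
                raise ValueError(f"probability for {cat!r} must be in (0, 1]")


#: Observed single-kernel pick-up success rates by seed shape.
FEEDER_PRESETS = {
    "round_corn": 0.92,
    "flat_corn": 0.90,
    "soybean": 0.974,
    "other_round_seed": 0.98,
}


def available_presets() -> list[str]:
    pkg = resources.files("seednmr") / "presets"
    return sorted(p.name.removesuffix(".json") for p in pkg.iterdir() if p.name.endswith(".json"))


def load_preset(name_or_path: str) -> PopulationPreset:
    """Load a shipped preset by name, or any preset JSON by path."""
    path = Path(name_or_path)
    if path.suffix == ".json" and path.exists():
        return PopulationPreset.from_dict(json.loads(path.read_text()))
    pkg = resources.files("seednmr") / "presets" / f"{name_or_path}.json"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise FileNotFoundError(
            f"unknown preset {name_or_path!r}; available: {available_presets()}"
        ) from None
    return PopulationPreset.from_dict(json.loads(text))


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Gaussian draws resampled above ``lower``.

    All presets sit many sd above their truncation point, so resampling
    terminates immediately and shifts class means negligibly (< 0.1 %).
    """
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise RuntimeError("truncated sampling failed to converge; check preset")


def generate_population(
    preset: PopulationPreset, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw ``n`` labelled kernels from a population preset.

    Per kernel: class by the preset fractions; weight and OCR from the
    class Gaussians (truncated at 0.05 g and 0 % respectively); oil mass
    A = OCR * m * 10 mg; water mass from the WCR Gaussian the same way.
    Fully reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = list(preset.classes)
    fractions = [preset.classes[c].fraction for c in labels]
    cls = rng.choice(labels, size=n, p=fractions)
    mass = np.empty(n)
    ocr = np.empty(n)
    for label in labels:
        spec = preset.classes[label]
        idx = cls == label
        mass[idx] = _trunc_normal(
            rng, spec.weight_mean_g, spec.weight_sd_g, MIN_KERNEL_MASS_G, int(idx.sum())
        )
        ocr[idx] = _trunc_normal(rng, spec.ocr_mean_pct, spec.ocr_sd_pct, 0.0, int(idx.sum()))
    wcr = _trunc_normal(rng, preset.wcr_mean_pct, preset.wcr_sd_pct, 0.0, n)
    return pd.DataFrame(
        {
            "kernel_id": [f"{preset.name}-{i:05d}" for i in range(n)],
            "true_class": cls,
            "mass_g": mass,
            "oil_mass_mg": ocr * mass * 10.0,
            "water_mass_mg": wcr * mass * 10.0,
            "ocr_pct": ocr,
            "wcr_pct": wcr,
            "assigned_class": ["unsorted"] * n,
        }
    )


def screening_acquisition(
    te_ms: float = 7.5,
    noise_sd_v: float = 0.0,
    n_averages: int = 2,
    seed: int | None = None,
) -> AcquisitionConfig:
    """Default acquisition grid with the screening echo time included."""
    grid = np.sort(np.unique(np.append(default_echo_grid(), te_ms)))
    return AcquisitionConfig(
        echo_times_ms=tuple(grid),
        noise_sd_v=noise_sd_v,
        n_averages=n_averages,
        seed=seed,
    )


def reference_calibration(
    k_mg_per_v: float = 361.7, b_mg: float = 0.0
) -> CalibrationModel:
    """A fixed calibration line (default slope 361.7 mg/V, no background)."""
    return CalibrationModel(k_mg_per_v=k_mg_per_v, b_mg=b_mg, r_squared=1.0, n_points=0)


def population_to_signals(
    records: pd.DataFrame,
    calib: CalibrationModel,
    relax: RelaxationParams,
    acq: AcquisitionConfig,
) -> list[tuple[str, EchoTrain]]:
    """Forward-simulate an echo train per kernel from its oil/water masses.

    Inverts the calibration line, S = (A - b)/k, to get the oil and water
    signal amplitudes, then simulates the bi-exponential echo train.
    Per-kernel noise streams are spawned deterministically from
    ``acq.seed``, so the full pipeline is reproducible end to end.
    """
    if calib.k_mg_per_v <= 0:
        raise ValueError("calibration slope must be positive")
    children = np.random.SeedSequence(acq.seed).spawn(len(records))
    out = []
    for (_, row), child in zip(records.iterrows(), children):
        s_o = max((row["oil_mass_mg"] - calib.b_mg) / calib.k_mg_per_v, 0.0)
        s_w = max((row["water_mass_mg"] - calib.b_mg) / calib.k_mg_per_v, 0.0)
        comp = KernelComposition(oil_amplitude_v=s_o, water_amplitude_v=s_w)
        train = simulate_echo_train(comp, relax, acq, rng=np.random.default_rng(child))
        out.append((str(row["kernel_id"]), train))
    return out


def simulate_feeder(
    n_attempts: int,
    model: FeederModel | None = None,
    category: str = "round_corn",
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Bernoulli event stream of single-kernel pick-up attempts.

    Returns the per-attempt log (with the running retry count: consecutive
    failures since the last success) and a summary with the failure count
    and success rate in percent.
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    model = model or FeederModel()
    if category not in model.success_probability:
        raise ValueError(
            f"unknown category {category!r}; known: {sorted(model.success_probability)}"
        )
    p = model.success_probability[category]
    rng = np.random.default_rng(seed)
    success = rng.random(n_attempts) < p
    retries = np.zeros(n_attempts, dtype=int)
    run = 0
    for i, ok in enumerate(success):
        retries[i] = run
        run = 0 if ok else run + 1
    log = pd.DataFrame(
        {"attempt": np.arange(1, n_attempts + 1), "success": success, "retries_before": retries}
    )
    n_fail = int((~success).sum())
    summary = {
        "category": category,
        "n_attempts": n_attempts,
        "failures": n_fail,
        "success_rate_pct": 100.0 * (n_attempts - n_fail) / n_attempts,
    }
    return log, summary


def repeat_measurement(
    kernel,
    n_repeats: int,
    calib: CalibrationModel,
    relax: RelaxationParams,
    noise_sd_v: float,
    seed: int | None = None,
    te_ms: float = 7.5,
    n_averages: int = 2,
    correct: bool = True,
) -> tuple[np.ndarray, dict]:
    """Repeated full-pipeline OCR measurements of one fixed kernel.

    Each repeat simulates a freshly noised echo train, decomposes it at
    the screening echo time, calibrates to oil mass and divides by the
    kernel mass. Returns the OCR series and its min/max/mean/sd summary.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    row = kernel if isinstance(kernel, dict) else dict(kernel)
    df = pd.DataFrame([{**row, "kernel_id": row.get("kernel_id", "repeat")} for _ in range(n_repeats)])
    acq = screening_acquisition(
        te_ms=te_ms, noise_sd_v=noise_sd_v, n_averages=n_averages, seed=seed
    )
    ocrs = np.empty(n_repeats)
    for i, (_, train) in enumerate(population_to_signals(df, calib, relax, acq)):
        s_o = oil_amplitude_single_echo(train, te_ms, relax, correct=correct)
        s_o = max(s_o, 0.0)
        oil_mass = apply_calibration(calib, s_o)
        ocrs[i] = compute_ocr(oil_mass, row["mass_g"])
    summary = {
        "min": float(ocrs.min()),
        "max": float(ocrs.max()),
        "mean": float(ocrs.mean()),
        "sd": float(ocrs.std(ddof=1)),
    }
    return ocrs, summary
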