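"""Forward model of single-kernel spin-echo NMR observables.

A dried seed contains two proton pools with very different transverse
relaxation: oil (T2 of order 100 ms) and bound water (T2 below 1 ms).
The spin-echo amplitude therefore decays bi-exponentially,

    S(t) = S_o * exp(-t / T2_oil) + S_w * exp(-t / T2_water),

where ``S_o`` and ``S_w`` are signal amplitudes (volts) proportional to
the oil and water proton masses, and ``S(0) = S_o + S_w`` is measured
directly as the initial FID amplitude. At a sufficiently long echo time
(TE = 7.5 ms for T2_water = 0.75 ms) the water term is attenuated below
1e-4 of S_w, so the echo isolates the oil signal.

All times are in milliseconds and amplitudes in volts. Echo times are
*full* echo times t, the variable the decay law is written in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RelaxationParams",
    "KernelComposition",
    "AcquisitionConfig",
    "EchoTrain",
    "DEFAULT_INSTRUMENT_METADATA",
    "default_echo_grid",
    "biexp_signal",
    "water_attenuation_factor",
    "simulate_echo_train",
]

#: Spectrometer settings carried as provenance only, never used numerically.
DEFAULT_INSTRUMENT_METADATA = {
    "larmor_frequency_mhz": "22.06",
    "pulse_90_180_us": "4/8",
    "bandwidth_khz": "100",
    "recycle_time_ms": "500",
}


@dataclass(frozen=True)
class RelaxationParams:
    """Transverse relaxation times of the two seed proton pools (ms)."""

    t2_oil_ms: float = 100.0
    t2_water_ms: float = 0.75

    def __post_init__(self) -> None:
        if self.t2_oil_ms <= 0 or self.t2_water_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t2_oil_ms <= self.t2_water_ms:
            raise ValueError("t2_oil_ms must exceed t2_water_ms (oil is the slow pool)")


@dataclass(frozen=True)
class KernelComposition:
    """Oil and water signal amplitudes of one kernel (volts)."""

    oil_amplitude_v: float
    water_amplitude_v: float

    def __post_init__(self) -> None:
        if self.oil_amplitude_v < 0 or self.water_amplitude_v < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def total_amplitude_v(self) -> float:
        """S(0) = S_o + S_w, the FID amplitude."""
        return self.oil_amplitude_v + self.water_amplitude_v


def default_echo_grid() -> np.ndarray:
    """12 echo times log-spaced from 0.3 ms to 120 ms.

    Spans both relaxation regimes: several points inside the bound-water
    decay (t < ~2 ms) and several across the oil decay (t up to ~T2_oil).
    """
    return np.geomspace(0.3, 120.0, 12)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Echo-time grid and receiver-noise settings for one measurement.

    ``noise_sd_v`` is the single-shot receiver noise standard deviation;
    averaging ``n_averages`` accumulations reduces the recorded noise to
    ``noise_sd_v / sqrt(n_averages)``.
    """

    echo_times_ms: tuple[float, ...] = field(
        default_factory=lambda: tuple(default_echo_grid())
    )
    noise_sd_v: float = 0.0
    n_averages: int = 2
    seed: int | None = None
    instrument_metadata: dict = field(
        default_factory=lambda: dict(DEFAULT_INSTRUMENT_METADATA)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.echo_times_ms, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("echo_times_ms must be a non-empty 1-D sequence")
        if np.any(t <= 0):
            raise ValueError("echo times must be strictly positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.noise_sd_v < 0:
            raise ValueError("noise_sd_v must be >= 0")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        object.__setattr__(self, "echo_times_ms", tuple(float(x) for x in t))

    @property
    def recorded_noise_sd_v(self) -> float:
        return self.noise_sd_v / np.sqrt(self.n_averages)


@dataclass(frozen=True)
class EchoTrain:
    """One kernel's recorded observables: FID amplitude plus echo train."""

    fid_amplitude_v: float
    echo_times_ms: tuple[float, ...]
    echo_amplitudes_v: tuple[float, ...]
    noise_sd_v: float = 0.0

    def __post_init__(self) -> None:
        if len(self.echo_amplitudes_v) != len(self.echo_times_ms):
            raise ValueError("echo_amplitudes_v and echo_times_ms length mismatch")
        object.__setattr__(
            self, "echo_times_ms", tuple(float(x) for x in self.echo_times_ms)
        )
        object.__setattr__(
            self,
            "echo_amplitudes_v",
            tuple(float(x) for x in self.echo_amplitudes_v),
        )

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.echo_times_ms)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.asarray(self.echo_amplitudes_v)


def biexp_signal(
    composition: KernelComposition,
    relax: RelaxationParams,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Noiseless bi-exponential echo amplitude at full echo time ``t`` (ms).

    Returns ``S_o exp(-t/T2_oil) + S_w exp(-t/T2_water)``; at t = 0 this
    is the FID amplitude S(0).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("echo time t must be >= 0")
    out = composition.oil_amplitude_v * np.exp(
        -t_arr / relax.t2_oil_ms
    ) + composition.water_amplitude_v * np.exp(-t_arr / relax.t2_water_ms)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def water_attenuation_factor(te_ms: float, t2_water_ms: float) -> float:
    """Residual fraction of the water signal surviving at echo time ``te_ms``.

    ``exp(-te/T2_water)``; for TE = 7.5 ms and T2_water = 0.75 ms this is
    exp(-10) ~= 5e-5, the basis for single-echo oil isolation.
    """
    if te_ms <= 0 or t2_water_ms <= 0:
        raise ValueError("te_ms and t2_water_ms must be positive")
    return float(np.exp(-te_ms / t2_water_ms))


def simulate_echo_train(
    composition: KernelComposition,
    relax: RelaxationParams,
    acq: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> EchoTrain:
    """Simulate the recorded FID + echo amplitudes for one kernel.

    Additive i.i.d. Gaussian receiver noise of standard deviation
    ``noise_sd_v / sqrt(n_averages)`` is applied independently to the FID
    point and every echo. Reproducible given ``acq.seed`` (or an explicit
    ``rng``, which takes precedence).
    """
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    times = np.asarray(acq.echo_times_ms)
    clean = biexp_signal(composition, relax, times)
    sd = acq.recorded_noise_sd_v
    noise = rng.normal(0.0, sd, size=times.size + 1) if sd > 0 else np.zeros(times.size + 1)
    return EchoTrain(
        fid_amplitude_v=float(composition.total_amplitude_v + noise[0]),
        echo_times_ms=tuple(times),
        echo_amplitudes_v=tuple(np.asarray(clean) + noise[1:]),
        noise_sd_v=sd,
    )
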