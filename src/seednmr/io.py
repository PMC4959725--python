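"""CSV/JSON readers and writers for the pipeline's on-disk formats.

* echo-train CSV: ``kernel_id,time_ms,amplitude_v``; the ``time_ms = 0``
  row carries the FID amplitude.
* kernel-record CSV: ``kernel_id,true_class,mass_g,oil_mass_mg,
  water_mass_mg,ocr_pct,assigned_class``.
* calibration standards CSV: ``standard_id,signal_v,mass_mg``.
* config JSON: relaxation + acquisition settings.

All files are UTF-8 with '.' decimal separators and a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .signal_model import AcquisitionConfig, EchoTrain, RelaxationParams

__all__ = [
    "DataError",
    "write_echo_trains_csv",
    "read_echo_trains_csv",
    "write_kernel_csv",
    "read_kernel_csv",
    "read_standards_csv",
    "load_config_json",
    "dump_config_json",
]

KERNEL_COLUMNS = [
    "kernel_id",
    "true_class",
    "mass_g",
    "oil_mass_mg",
    "water_mass_mg",
    "ocr_pct",
    "assigned_class",
]


class DataError(ValueError):
    """A data file is missing, malformed or inconsistent."""


def write_echo_trains_csv(trains: list[tuple[str, EchoTrain]], path) -> None:
    rows = []
    for kernel_id, train in trains:
        rows.append({"kernel_id": kernel_id, "time_ms": 0.0, "amplitude_v": train.fid_amplitude_v})
        for t, a in zip(train.echo_times_ms, train.echo_amplitudes_v):
            rows.append({"kernel_id": kernel_id, "time_ms": t, "amplitude_v": a})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_echo_trains_csv(path) -> list[tuple[str, EchoTrain]]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot read echo-train CSV {path}: {exc}") from exc
    required = {"kernel_id", "time_ms", "amplitude_v"}
    if not required.issubset(df.columns):
        raise DataError(f"echo-train CSV {path} missing columns {required - set(df.columns)}")
    out = []
    for kernel_id, sub in df.groupby("kernel_id", sort=False):
        sub = sub.sort_values("time_ms")
        fid = sub[sub["time_ms"] == 0.0]
        if len(fid) != 1:
            raise DataError(f"kernel {kernel_id!r}: expected exactly one time_ms=0 (FID) row")
        echoes = sub[sub["time_ms"] > 0.0]
        out.append(
            (
                str(kernel_id),
                EchoTrain(
                    fid_amplitude_v=float(fid["amplitude_v"].iloc[0]),
                    echo_times_ms=tuple(echoes["time_ms"]),
                    echo_amplitudes_v=tuple(echoes["amplitude_v"]),
                ),
            )
        )
    return out


def write_kernel_csv(records: pd.DataFrame, path) -> None:
    records[KERNEL_COLUMNS].to_csv(path, index=False)


def read_kernel_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot read kernel CSV {path}: {exc}") from exc
    missing = set(KERNEL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"kernel CSV {path} missing columns {sorted(missing)}")
    return df


def read_standards_csv(path) -> pd.DataFrame:
    """Read calibration standards, reporting the first malformed line."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"standards file not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise DataError(f"standards CSV {path} is empty")
    header = [h.strip() for h in lines[0].split(",")]
    if header != ["standard_id", "signal_v", "mass_mg"]:
        raise DataError(
            f"standards CSV {path} line 1: expected header "
            f"'standard_id,signal_v,mass_mg', got {lines[0]!r}"
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise DataError(f"standards CSV {path} line {lineno}: expected 3 fields")
        try:
            rows.append(
                {"standard_id": parts[0].strip(), "signal_v": float(parts[1]), "mass_mg": float(parts[2])}
            )
        except ValueError as exc:
            raise DataError(f"standards CSV {path} line {lineno}: {exc}") from None
    if not rows:
        raise DataError(f"standards CSV {path} contains no data rows")
    return pd.DataFrame(rows)


def load_config_json(path) -> tuple[RelaxationParams, AcquisitionConfig]:
    try:
        cfg = json.loads(Path(path).read_text(encoding="utf-8"))
        relax = RelaxationParams(
            t2_oil_ms=cfg["relaxation"]["t2_oil_ms"],
            t2_water_ms=cfg["relaxation"]["t2_water_ms"],
        )
        a = cfg["acquisition"]
        acq = AcquisitionConfig(
            echo_times_ms=tuple(a["echo_times_ms"]),
            noise_sd_v=a.get("noise_sd_v", 0.0),
            n_averages=a.get("n_averages", 2),
            seed=a.get("seed"),
        )
    except DataError:
        raise
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise DataError(f"bad config JSON {path}: {exc}") from exc
    return relax, acq


def dump_config_json(relax: RelaxationParams, acq: AcquisitionConfig, path) -> None:
    cfg = {
        "relaxation": {"t2_oil_ms": relax.t2_oil_ms, "t2_water_ms": relax.t2_water_ms},
        "acquisition": {
            "echo_times_ms": list(acq.echo_times_ms),
            "noise_sd_v": acq.noise_sd_v,
            "n_averages": acq.n_averages,
            "seed": acq.seed,
        },
    }
    Path(path).write_text(json.dumps(cfg, indent=2), encoding="utf-8")
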