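"""Readers/writers for the package's columnar text formats plus run config.

Formats:

* traces: CSV with columns ``motor_nm, transducer_nm[, force_pN]`` and a
  JSON sidecar ``{sampling_rate, stiffness, ATP_uM, mode}`` at
  ``<path>.json``;
* events/durations/pairs: TSV (events carry a ``# dead_time_s=`` header);
* transients: two-column CSV (``time_s, signal_au``) with a JSON sidecar
  ``{kind, split_timebase}``;
* gliding tables: TSV with columns
  ``filament_id, frames, velocity_um_s, fraction_slow``.

Round-trips are lossless to the stated float precision (17 significant
digits, i.e. exact for doubles).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .datatypes import Event, EventSet, Transient, TrapTrace

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_transient",
    "write_transient",
    "read_gliding",
    "write_gliding",
]

_FLOAT_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: TrapTrace, path: str | Path) -> Path:
    """Write a trace as CSV plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    cols = {"motor_nm": trace.motor_pos, "transducer_nm": trace.transducer_pos}
    if trace.force is not None:
        cols["force_pN"] = trace.force
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "sampling_rate": trace.sampling_rate,
        "stiffness": list(trace.stiffness),
        "ATP_uM": trace.atp,
        "mode": trace.mode,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> TrapTrace:
    """Read a trace CSV + sidecar; validates channels and metadata."""
    path = Path(path)
    sc = _sidecar(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar {sc}")
    meta = json.loads(sc.read_text())
    for key in ("sampling_rate", "mode"):
        if key not in meta:
            raise ValueError(f"sidecar missing {key}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("motor_nm", "transducer_nm"):
        if col not in df:
            raise ValueError(f"trace missing column {col}")
        bad = np.flatnonzero(df[col].isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(f"NaN in column {col} at line {bad[0] + 2}")
    force = None
    if "force_pN" in df:
        if meta["mode"] == "unloaded":
            warnings.warn("force column present in unloaded mode; ignored")
        else:
            force = df["force_pN"].to_numpy(dtype=float)
    return TrapTrace(
        motor_pos=df["motor_nm"].to_numpy(dtype=float),
        transducer_pos=df["transducer_nm"].to_numpy(dtype=float),
        sampling_rate=float(meta["sampling_rate"]),
        force=force,
        atp=float(meta.get("ATP_uM", float("nan"))),
        mode=meta["mode"],
        stiffness=tuple(meta.get("stiffness", (0.08, 0.08))),
    )


def write_events(events: EventSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dead_time_s={events.dead_time!r}\n")
        events.to_frame().to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_events(path: str | Path) -> EventSet:
    path = Path(path)
    dead_time = 0.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# dead_time_s="):
            dead_time = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    events = [
        Event(
            start=row.start_s,
            stop=row.stop_s,
            substep1=row.substep1_nm,
            substep2=row.substep2_nm,
            total_step=row.total_step_nm,
            mean_force=row.mean_force_pN,
        )
        for row in df.itertuples()
    ]
    return EventSet(events=events, dead_time=dead_time, source={"path": str(path)})


def write_transient(tr: Transient, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": tr.time, "signal_au": tr.signal}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    meta = {
        "kind": tr.kind,
        "split_timebase": list(tr.split_timebase) if tr.split_timebase else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_transient(path: str | Path) -> Transient:
    path = Path(path)
    sc = _sidecar(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar {sc}")
    meta = json.loads(sc.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    return Transient(
        time=df["time_s"].to_numpy(dtype=float),
        signal=df["signal_au"].to_numpy(dtype=float),
        kind=meta.get("kind", "pyrene"),
        split_timebase=meta.get("split_timebase"),
    )


def write_gliding(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_gliding(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = {"filament_id", "frames", "velocity_um_s", "fraction_slow"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"gliding table missing columns {sorted(missing)}")
    return df


class RunConfig(BaseModel):
    """Validated top-level pipeline configuration.

    Stage-specific parameters nest under the per-recipe dicts; unknown
    top-level keys are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    kT: float = Field(4.05, gt=0)  # pN*nm
    dead_time: float = Field(0.016, gt=0)  # s
    covariance_window: float = Field(0.008, gt=0)  # s
    bootstrap_n: int = Field(1000, ge=0)
    output_dir: str = "."
    simulate: dict = Field(default_factory=dict)
    detect: dict = Field(default_factory=dict)
    mech: dict = Field(default_factory=dict)
    lifetimes: dict = Field(default_factory=dict)
    transient: dict = Field(default_factory=dict)
    atpase: dict = Field(default_factory=dict)
    gliding: dict = Field(default_factory=dict)
    turnover: dict = Field(default_factory=dict)
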