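"""File formats and run manifests.

CSV for pressure traces (columns ``time_s``, ``overpressure_pa``) and
cohorts, long-format CSV for physiology, JSON for reports, HDF5 for field
snapshots.  All physical quantities carry SI units in column/key names.
Write-then-read round trips are identities on values (floats preserved to
full precision via repr-style formatting).
"""

from __future__ import annotations

import hashlib
import json
import platform
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .injury_stats import Cohort, parse_cohort
from .waveform import PressureTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_cohort_csv",
    "read_long_physiology",
    "write_long_physiology",
    "write_snapshot_h5",
    "read_snapshot_h5",
    "write_json",
    "RunManifest",
    "roundtrip_trace",
    "roundtrip_cohort",
]


def read_trace_csv(path) -> PressureTrace:
    """Read a pressure trace CSV (time_s, overpressure_pa [, probe_id])."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    for col in ("time_s", "overpressure_pa"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} lacks column {col!r}")
    pid = str(df["probe_id"].iloc[0]) if "probe_id" in df.columns else ""
    return PressureTrace(time=df["time_s"].to_numpy(dtype=float),
                         overpressure=df["overpressure_pa"].to_numpy(dtype=float),
                         probe_id=pid)


def write_trace_csv(trace: PressureTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.time,
                       "overpressure_pa": trace.overpressure})
    if trace.probe_id:
        df["probe_id"] = trace.probe_id
    df.to_csv(path, index=False, float_format="%.17g")


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort in the same schema the parser reads."""
    order = ("LH", "hemothorax", "splenic", "liver", "BR", "IAH")
    label = {"LH": "LH", "hemothorax": "Hemothorax",
             "splenic": "Splenic injury", "liver": "Liver injury",
             "BR": "BR", "IAH": "IAH"}
    rows = []
    for r in cohort:
        remarks = ", ".join(label[f] for f in order if f in r.organ_flags)
        rows.append({
            "id": r.animal_id,
            "body_weight_kg": r.body_weight,
            "body_armor": "Yes" if r.armor else "No",
            "organ_damage": remarks,
            "respiratory_arrest": "Yes" if r.respiratory_arrest else "No",
            "outcome": r.outcome.capitalize(),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_long_physiology(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"subject", "group", "time", "variable", "value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"physiology CSV lacks columns {sorted(missing)}")
    return df


def write_long_physiology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_snapshot_h5(path, grid, snapshots, gamma: float = 1.4) -> None:
    """Write field snapshots (list of (time, AxiField)) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("z_edges_m", data=grid.z_edges)
        f.create_dataset("r_edges_m", data=grid.r_edges)
        f.create_dataset("solid", data=grid.solid)
        f.attrs["gamma"] = gamma
        for k, (t, fld) in enumerate(snapshots):
            g = f.create_group(f"snapshot_{k:04d}")
            g.attrs["time_s"] = t
            g.create_dataset("conserved", data=fld.U)


def read_snapshot_h5(path):
    """Read snapshots back: (z_edges, r_edges, solid, [(time, U), ...])."""
    with h5py.File(path, "r") as f:
        z = f["z_edges_m"][:]
        r = f["r_edges_m"][:]
        solid = f["solid"][:].astype(bool)
        snaps = []
        for key in sorted(k for k in f.keys() if k.startswith("snapshot_")):
            snaps.append((float(f[key].attrs["time_s"]),
                          f[key]["conserved"][:]))
    return z, r, solid, snaps


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


@dataclass
class RunManifest:
    """Reproducibility record written at the end of simulate/synth runs."""

    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    package_version: str = ""
    python: str = field(default_factory=platform.python_version)
    wall_clock_start: str = ""
    wall_clock_end: str = ""

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, path) -> None:
        """Atomic write (temp file then rename)."""
        tmp = Path(str(path) + ".tmp")
        self.wall_clock_end = _time.strftime("%Y-%m-%dT%H:%M:%S")
        tmp.write_text(json.dumps(asdict(self), indent=2, default=_jsonable)
                       + "\n")
        tmp.replace(path)


def roundtrip_trace(trace: PressureTrace, path) -> PressureTrace:
    """Write then re-read a trace; values survive to 1e-12 relative."""
    write_trace_csv(trace, path)
    return read_trace_csv(path)


def roundtrip_cohort(path_in, path_out) -> Cohort:
    """Parse, serialise and re-parse a cohort file."""
    cohort = parse_cohort(path_in)
    write_cohort_csv(cohort, path_out)
    return parse_cohort(path_out)
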