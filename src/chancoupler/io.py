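"""Delimited-table I/O with schema validation.

All interchange is plain text: comma- or tab-delimited tables (auto-detected,
UTF-8) plus a JSON metadata sidecar for episodic sweep data. Units are fixed
by schema: time in ms (sweeps) or s (bleach traces), current in pA, voltage
in mV. Values round-trip at 6 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .biophys import GatingCurve
from .stoichiometry import DoseResponse
from .synthgen import BleachTrace, GatingModel, StepProtocol, SweepSet

__all__ = [
    "SCHEMAS",
    "load_table",
    "write_sweepset",
    "read_sweepset",
    "write_bleach_traces",
    "read_bleach_traces",
    "write_dose_response",
    "read_dose_response",
    "write_gating_curve",
    "read_gating_curve",
]

SCHEMAS: dict[str, list[str]] = {
    "sweeps": ["sweep_id", "time_ms", "current_pA"],
    "bleach": ["molecule_id", "frame", "intensity"],
    "dose_response": ["ratio", "y", "sem"],
    "gating": ["voltage_mV", "response"],
    "fret": ["roi_id", "fret", "cfp", "yfp"],
}

_FLOAT_FMT = "%.6g"


def load_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    The delimiter (comma or tab) is sniffed from the header line. Missing
    columns, non-numeric cells and duplicated (sweep_id, time_ms) keys are
    rejected with row-numbered messages.
    """
    path = Path(path)
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; one of {sorted(SCHEMAS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    header = path.open(encoding="utf-8").readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    required = SCHEMAS[schema_name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r} at data row {bad[0] + 1}"
            )
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0]) + 1
            raise ValueError(f"{path.name}: empty cell in column {col!r} at data row {row}")
        df[col] = numeric
    if schema_name == "sweeps":
        dup = df.duplicated(subset=["sweep_id", "time_ms"])
        if dup.any():
            row = int(df.index[dup][0]) + 1
            raise ValueError(f"{path.name}: duplicated (sweep_id, time_ms) key at data row {row}")
    return df


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_sweepset(sweeps: SweepSet, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write sweeps in long format plus a JSON metadata sidecar."""
    path = Path(path)
    n_sweeps, n_samples = sweeps.sweeps.shape
    t = sweeps.time_ms
    df = pd.DataFrame(
        {
            "sweep_id": np.repeat(np.arange(n_sweeps), n_samples),
            "time_ms": np.tile(t, n_sweeps),
            "current_pA": sweeps.sweeps.ravel(),
        }
    )
    _write_df(df, path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".meta.json")
    meta = {
        "protocol": asdict(sweeps.protocol),
        "model": asdict(sweeps.model) if sweeps.model else None,
        "seed": sweeps.seed,
    }
    sidecar.write_text(json.dumps(meta, indent=2), encoding="utf-8")


def read_sweepset(path: str | Path, sidecar: str | Path | None = None) -> SweepSet:
    path = Path(path)
    df = load_table(path, "sweeps")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    protocol = StepProtocol(**meta["protocol"])
    model = GatingModel(**meta["model"]) if meta.get("model") else None
    mat = (
        df.sort_values(["sweep_id", "time_ms"])["current_pA"]
        .to_numpy()
        .reshape(df["sweep_id"].nunique(), -1)
    )
    return SweepSet(sweeps=mat, protocol=protocol, model=model, seed=meta.get("seed"))


def write_bleach_traces(traces: list[BleachTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(tr.intensity.size),
                    "intensity": tr.intensity,
                }
            )
        )
    _write_df(pd.concat(frames, ignore_index=True), Path(path))


def read_bleach_traces(path: str | Path, frame_interval_s: float) -> list[BleachTrace]:
    df = load_table(path, "bleach")
    out = []
    for mol, grp in df.groupby("molecule_id"):
        out.append(
            BleachTrace(
                molecule_id=int(mol),
                intensity=grp.sort_values("frame")["intensity"].to_numpy(),
                frame_interval_s=frame_interval_s,
            )
        )
    return out


def write_dose_response(dr: DoseResponse, path: str | Path) -> None:
    _write_df(pd.DataFrame({"ratio": dr.x, "y": dr.y, "sem": dr.sem}), Path(path))


def read_dose_response(path: str | Path) -> DoseResponse:
    df = load_table(path, "dose_response").sort_values("ratio")
    return DoseResponse(
        x=df["ratio"].to_numpy(), y=df["y"].to_numpy(), sem=df["sem"].to_numpy()
    )


def write_gating_curve(curve: GatingCurve, path: str | Path) -> None:
    _write_df(
        pd.DataFrame({"voltage_mV": curve.voltages, "response": curve.response}),
        Path(path),
    )


def read_gating_curve(path: str | Path, kind: str = "activation") -> GatingCurve:
    df = load_table(path, "gating").sort_values("voltage_mV")
    return GatingCurve(
        voltages=df["voltage_mV"].to_numpy(), response=df["response"].to_numpy(), kind=kind
    )
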