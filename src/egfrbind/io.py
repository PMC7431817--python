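"""CSV/JSON plumbing for curves, bleach series and multi-dataset designs.

Formats:

* binding curve CSV — header ``conc_nM,intensity,sem`` (``sem`` optional);
* bleach series CSV — header ``s,r,sd`` (``sd`` optional);
* design manifest CSV — header ``condition,gate,Rtot,curve_file`` with
  ``curve_file`` paths resolved relative to the manifest's directory;
* structured results — JSON with a ``schema_version`` field, numbers at
  full ``repr`` precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .globalfit import DesignCell
from .hill import BindingCurve
from .homofret import BleachSeries

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_bleach_csv",
    "write_bleach_csv",
    "read_design",
    "write_design",
    "write_json",
    "read_json",
]


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"found {list(df.columns)}")


def read_curve_csv(path, label: str | None = None) -> BindingCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["conc_nM", "intensity"], path)
    for col in ("conc_nM", "intensity"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric/missing {col} at row {bad[0]}")
    sem = df["sem"].to_numpy(float) if "sem" in df.columns else None
    return BindingCurve(
        conc=df["conc_nM"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        sem=sem,
        label=label if label is not None else str(path),
    )


def write_curve_csv(curve: BindingCurve, path) -> None:
    data = {"conc_nM": curve.conc, "intensity": curve.intensity}
    if curve.sem is not None:
        data["sem"] = curve.sem
    pd.DataFrame(data).to_csv(path, index=False)


def read_bleach_csv(path, label: str | None = None) -> BleachSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["s", "r"], path)
    sd = df["sd"].to_numpy(float) if "sd" in df.columns else None
    return BleachSeries(
        s=df["s"].to_numpy(float),
        r=df["r"].to_numpy(float),
        sd=sd,
        label=label if label is not None else str(path),
    )


def write_bleach_csv(series: BleachSeries, path) -> None:
    data = {"s": series.s, "r": series.r}
    if series.sd is not None:
        data["sd"] = series.sd
    pd.DataFrame(data).to_csv(path, index=False)


def read_design(manifest_path) -> list[DesignCell]:
    """Load a multi-dataset design from a manifest CSV plus per-curve CSVs."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    _require_columns(df, ["condition", "gate", "Rtot", "curve_file"], manifest_path)
    cells = []
    for i, row in df.iterrows():
        curve_path = manifest_path.parent / str(row["curve_file"])
        try:
            rtot = float(row["Rtot"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"{manifest_path}: non-numeric Rtot at row {i}"
            ) from None
        cells.append(DesignCell(
            condition=str(row["condition"]),
            gate=str(row["gate"]),
            Rtot=rtot,
            curve=read_curve_csv(curve_path, label=f"{row['condition']}/{row['gate']}"),
        ))
    return cells


def write_design(cells: Sequence[DesignCell], directory) -> Path:
    """Write per-curve CSVs plus a ``design.csv`` manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for cell in cells:
        fname = f"{cell.condition}_{cell.gate}.csv"
        write_curve_csv(cell.curve, directory / fname)
        rows.append({"condition": cell.condition, "gate": cell.gate,
                     "Rtot": cell.Rtot, "curve_file": fname})
    manifest = directory / "design.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj: dict, path, schema_version: int = 1) -> None:
    payload = {"schema_version": schema_version, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
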