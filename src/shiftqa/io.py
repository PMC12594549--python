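"""Plain-text exchange formats.

Dose-grid format (whitespace-separated, one header item per line):

    nx ny            number of columns (RL) and rows (SI)
    spacing_si spacing_rl
    origin_si origin_rl
    unit
    <ny rows of nx dose values>

Measurement CSV: header ``pos_si_mm,pos_rl_mm,dose`` and one row per
sample; an optional sidecar (``key: value`` lines) carries acquisition
metadata.  Schedule files are ``key value`` lines plus the offset list.
All writers round-trip losslessly at 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detector import Measurement
from .grids import DoseGrid
from .virtualgrid import ShiftSchedule

__all__ = [
    "write_dose_grid",
    "read_dose_grid",
    "write_measurement",
    "read_measurement",
    "write_schedule",
    "read_schedule",
    "read_dicom_dose",
]

_FMT = "%.9g"


def write_dose_grid(grid: DoseGrid, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{grid.n_rl} {grid.n_si}\n")
        fh.write(f"{grid.spacing[0]:.9g} {grid.spacing[1]:.9g}\n")
        fh.write(f"{grid.origin[0]:.9g} {grid.origin[1]:.9g}\n")
        fh.write(f"{grid.unit}\n")
        np.savetxt(fh, grid.values, fmt=_FMT)


class ParseError(ValueError):
    """Malformed header or body; message carries the 1-based line number."""


def _parse_floats(line: str, n: int, lineno: int, what: str) -> list[float]:
    parts = line.split()
    if len(parts) != n:
        raise ParseError(f"line {lineno}: expected {n} {what} value(s), got {len(parts)}")
    try:
        return [float(p) for p in parts]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def read_dose_grid(path) -> DoseGrid:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 4:
        raise ParseError("line 1: dose-grid file needs a 4-line header")
    dims = lines[0].split()
    if len(dims) != 2:
        raise ParseError("line 1: expected 'nx ny'")
    try:
        nx, ny = int(dims[0]), int(dims[1])
    except ValueError:
        raise ParseError("line 1: nx and ny must be integers") from None
    sp = _parse_floats(lines[1], 2, 2, "spacing")
    og = _parse_floats(lines[2], 2, 3, "origin")
    unit = lines[3].strip()
    if unit not in ("percent", "Gy"):
        raise ParseError(f"line 4: unknown unit {unit!r}")
    body = lines[4:]
    if len(body) < ny:
        raise ParseError(f"line {len(lines)}: expected {ny} data rows, got {len(body)}")
    values = np.empty((ny, nx))
    for i, line in enumerate(body[:ny]):
        values[i] = _parse_floats(line, nx, 5 + i, "dose")
    return DoseGrid(values=values, spacing=(sp[0], sp[1]), origin=(og[0], og[1]), unit=unit)


def write_measurement(meas: Measurement, path, sidecar: bool = True) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"pos_si_mm": meas.pos_si, "pos_rl_mm": meas.pos_rl, "dose": meas.dose}
    )
    df.to_csv(path, index=False, float_format=_FMT, lineterminator="\n")
    if sidecar:
        side = path.with_suffix(path.suffix + ".meta")
        with side.open("w") as fh:
            for key, val in meas.meta.items():
                if key == "sources":
                    continue
                fh.write(f"{key}: {val}\n")


def read_measurement(path) -> Measurement:
    df = pd.read_csv(path)
    required = ["pos_si_mm", "pos_rl_mm", "dose"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"line 1: measurement CSV missing column(s) {missing}")
    if df["dose"].lt(0).any():
        bad = int(df.index[df["dose"] < 0][0]) + 2  # +header +1-based
        raise ParseError(f"line {bad}: negative dose rejected")
    meta = {}
    side = Path(str(path) + ".meta")
    if side.exists():
        for line in side.read_text().splitlines():
            if ":" in line:
                key, _, val = line.partition(":")
                meta[key.strip()] = val.strip()
        if "shift" in meta:
            meta["shift"] = tuple(
                float(t) for t in meta["shift"].strip("() ").split(",") if t.strip()
            )
    return Measurement(
        pos_si=df["pos_si_mm"].to_numpy(),
        pos_rl=df["pos_rl_mm"].to_numpy(),
        dose=df["dose"].to_numpy(),
        meta=meta,
    )


def write_schedule(schedule: ShiftSchedule, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"axis {schedule.axis}\n")
        fh.write(f"native_pitch_mm {schedule.native_pitch:.9g}\n")
        fh.write(f"target_spacing_mm {schedule.target_spacing:.9g}\n")
        fh.write(f"uniform {int(schedule.uniform)}\n")
        fh.write("offsets_mm " + " ".join(f"{o:.9g}" for o in schedule.offsets) + "\n")


def read_schedule(path) -> ShiftSchedule:
    fields: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        key, _, val = line.partition(" ")
        if not val:
            raise ParseError(f"line {lineno}: expected 'key value'")
        fields[key] = val
    try:
        return ShiftSchedule(
            axis=fields["axis"],
            offsets=tuple(float(o) for o in fields["offsets_mm"].split()),
            target_spacing=float(fields["target_spacing_mm"]),
            native_pitch=float(fields["native_pitch_mm"]),
            uniform=bool(int(fields.get("uniform", "1"))),
        )
    except KeyError as exc:
        raise ParseError(f"line 1: schedule file missing field {exc}") from None


def read_dicom_dose(path, plane_index: int | None = None) -> DoseGrid:
    """Optional DICOM RT Dose import (single 2D plane).

    Extension point; requires :mod:`pydicom`.  The first (or indexed) frame
    of the dose grid is mapped onto the package's SI/RL frame with the
    image rows as SI and columns as RL.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading DICOM RT Dose requires pydicom") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array * float(getattr(ds, "DoseGridScaling", 1.0))
    if arr.ndim == 3:
        arr = arr[plane_index or 0]
    rowsp, colsp = (float(x) for x in ds.PixelSpacing)
    ipp = [float(x) for x in ds.ImagePositionPatient]
    return DoseGrid(
        values=np.asarray(arr, dtype=float),
        spacing=(rowsp, colsp),
        origin=(ipp[1], ipp[0]),
        unit="Gy",
        meta={"source": "dicom"},
    )
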