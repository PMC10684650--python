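"""Readers and writers for hyperspectral maps and annotation masks.

Two dialects are supported:

``long_text``
    UTF-8 tab-separated values with a header row and the columns
    ``x_um  y_um  wavenumber_cm1  intensity`` — one row per (pixel,
    wavenumber) pair.  Human-readable and diff-friendly; the axis is
    repeated for every pixel.

``container``
    A single HDF5 file with datasets ``axis`` (n,), ``cube`` (h, w, n) and
    optionally ``mask`` (h, w), plus a ``step_um`` attribute.  The axis is
    stored once, so the file is far smaller than the long-text form.

Instruments commonly emit descending wavenumber axes; both readers re-sort
to ascending order.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import HyperspectralMap, WavenumberAxis, validate_mask

__all__ = ["read_map", "write_map", "read_mask", "write_mask", "MapFormatError"]

LONG_TEXT_COLUMNS = ["x_um", "y_um", "wavenumber_cm1", "intensity"]


class MapFormatError(ValueError):
    """Raised when a map file violates the dialect it claims to be in."""


def _detect_format(path: Path) -> str:
    if h5py.is_hdf5(path):
        return "container"
    return "long_text"


def read_map(path: str | Path, format: str | None = None) -> HyperspectralMap:
    """Read a hyperspectral map; ``format`` is auto-detected when omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "container":
        return _read_container(path)
    if fmt == "long_text":
        return _read_long_text(path)
    raise ValueError(f"unknown map format: {fmt!r}")


def write_map(hmap: HyperspectralMap, path: str | Path, format: str = "long_text") -> Path:
    """Write a map in the named dialect; returns the path written."""
    path = Path(path)
    if format == "container":
        _write_container(hmap, path)
    elif format == "long_text":
        _write_long_text(hmap, path)
    else:
        raise ValueError(f"unknown map format: {format!r}")
    return path


def _read_long_text(path: Path) -> HyperspectralMap:
    try:
        frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MapFormatError(f"{path}: cannot parse as long_text TSV: {exc}") from exc
    if list(frame.columns) != LONG_TEXT_COLUMNS:
        raise MapFormatError(
            f"{path}: expected columns {LONG_TEXT_COLUMNS}, found {list(frame.columns)}"
        )
    if frame.empty:
        # Header-only file: the empty 0x0 map.
        return HyperspectralMap(
            axis=WavenumberAxis(np.array([1.0, 2.0])),
            cube=np.zeros((0, 0, 2)),
        )
    numeric = pd.DataFrame(index=frame.index)
    for col in LONG_TEXT_COLUMNS:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise MapFormatError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        # Python's float parser is exactly round-trippable against repr();
        # pandas' fast path can be off by one ulp.
        numeric[col] = frame[col].map(float)

    xs = np.sort(numeric["x_um"].unique())
    ys = np.sort(numeric["y_um"].unique())
    wns = np.sort(numeric["wavenumber_cm1"].unique())
    expected = len(xs) * len(ys) * len(wns)
    if len(numeric) != expected:
        raise MapFormatError(
            f"{path}: ragged grid — {len(numeric)} rows, expected "
            f"{len(xs)}x{len(ys)}x{len(wns)} = {expected}"
        )
    axis = WavenumberAxis(wns)
    col_of = {x: i for i, x in enumerate(xs)}
    row_of = {y: i for i, y in enumerate(ys)}
    band_of = {w: i for i, w in enumerate(wns)}
    cube = np.full((len(ys), len(xs), len(wns)), np.nan)
    rows = numeric["y_um"].map(row_of).to_numpy()
    cols = numeric["x_um"].map(col_of).to_numpy()
    bands = numeric["wavenumber_cm1"].map(band_of).to_numpy()
    cube[rows, cols, bands] = numeric["intensity"].to_numpy()
    if np.isnan(cube).any():
        raise MapFormatError(f"{path}: ragged grid — duplicate or missing (pixel, wavenumber) rows")
    step = float(xs[1] - xs[0]) if len(xs) > 1 else (float(ys[1] - ys[0]) if len(ys) > 1 else 1.0)
    return HyperspectralMap(axis=axis, cube=cube, step_um=step or 1.0)


def _write_long_text(hmap: HyperspectralMap, path: Path) -> None:
    buf = _io.StringIO()
    buf.write("\t".join(LONG_TEXT_COLUMNS) + "\n")
    x_um, y_um = hmap.coords()
    wn = hmap.axis.values
    for r in range(hmap.height):
        for c in range(hmap.width):
            intens = hmap.cube[r, c]
            x, y = x_um[r, c], y_um[r, c]
            for w, v in zip(wn, intens):
                buf.write(f"{x:.6g}\t{y:.6g}\t{float(w)!r}\t{float(v)!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def _read_container(path: Path) -> HyperspectralMap:
    with h5py.File(path, "r") as f:
        if "axis" not in f or "cube" not in f:
            raise MapFormatError(f"{path}: container missing 'axis' or 'cube' dataset")
        axis_values = np.asarray(f["axis"])
        cube = np.asarray(f["cube"])
        mask = np.asarray(f["mask"]) if "mask" in f else None
        step = float(f.attrs.get("step_um", 1.0))
    order = np.argsort(axis_values)
    axis_values = axis_values[order]
    cube = cube[..., order]
    return HyperspectralMap(
        axis=WavenumberAxis(axis_values), cube=cube, step_um=step, mask=mask
    )


def _write_container(hmap: HyperspectralMap, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("axis", data=hmap.axis.values)
        f.create_dataset("cube", data=hmap.cube)
        if hmap.mask is not None:
            f.create_dataset("mask", data=hmap.mask)
        f.attrs["step_um"] = hmap.step_um


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask sidecar: tab-separated integers, one text row per map row."""
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            rows.append([int(tok) for tok in line.split("\t")])
    if rows and any(len(r) != len(rows[0]) for r in rows):
        raise MapFormatError(f"{path}: ragged mask rows")
    return validate_mask(np.asarray(rows, dtype=np.int64))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    mask = validate_mask(mask)
    path = Path(path)
    lines = ["\t".join(str(int(v)) for v in row) for row in mask]
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path
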