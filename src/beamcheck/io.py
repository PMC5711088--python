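"""Domain containers and text-format I/O for beam scan data.

Three kinds of objects travel through the pipeline:

* :class:`ScanCurve` — one 1D dose scan (a percent-depth-dose curve along
  the beam axis, or a lateral profile at a fixed depth) together with its
  acquisition geometry.
* :class:`DoseGrid` — a regular 2D or 3D dose array with physical origin
  and spacing, used by the gamma engine and chamber-ROI extraction.
* :class:`PointDoseRecord` — one patient's point-dose triplet from the
  treatment planning system (TPS), the verification system (VS) and an
  ion chamber (IC).

All on-disk formats are plain UTF-8 text: comma-separated tables with
``#`` comment lines for curves and point doses, and a small headered
matrix format for dose grids.  DICOM RT Dose files can additionally be
read (never written) for convenience.

Units: positions and geometry in mm; grid dose in Gy; curve values in
raw scanner units as stored — the percent scales used by the analysis
are produced by the normalization operations in :mod:`beamcheck.curves`,
never by the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from beamcheck.errors import DataError, FormatError, ParseError

log = logging.getLogger(__name__)

AXES = ("depth", "crossline", "inline")
COLLIMATIONS = ("jaw", "mlc")
SOURCES = ("measured", "tps", "vs", "synthetic")
TECHNIQUES = ("IMRT", "VMAT")

_FLOAT_FMT = "%.12g"  # round trips to better than 1e-9 relative


@dataclass
class ScanCurve:
    """One measured or calculated 1D dose curve with geometry metadata.

    Parameters
    ----------
    axis
        ``"depth"`` for a PDD along the beam central axis, ``"crossline"``
        or ``"inline"`` for a lateral profile.
    positions, values
        Sample locations (mm) and doses.  Positions must be strictly
        increasing; values finite and non-negative.
    energy_label
        Beam energy tag, e.g. ``"6x"``.
    field_x, field_y
        Field size (mm) along crossline / inline at the nominal SSD plane.
    ssd
        Source-to-surface distance (mm).
    scan_depth
        Depth (mm) of a lateral profile; must be ``None`` for PDDs.
    collimation
        ``"jaw"`` or ``"mlc"`` — which device defines ``field_x``/``field_y``.
    source
        ``"measured"``, ``"tps"``, ``"vs"`` or ``"synthetic"``.
    """

    axis: str
    positions: np.ndarray
    values: np.ndarray
    energy_label: str
    field_x: float
    field_y: float
    ssd: float = 1000.0
    scan_depth: float | None = None
    collimation: str = "jaw"
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis not in AXES:
            raise DataError(f"unknown axis {self.axis!r}; expected one of {AXES}")
        if self.collimation not in COLLIMATIONS:
            raise DataError(f"unknown collimation {self.collimation!r}")
        if self.source not in SOURCES:
            raise DataError(f"unknown source {self.source!r}")
        if self.positions.ndim != 1 or self.values.ndim != 1:
            raise DataError("positions and values must be 1D")
        if len(self.positions) != len(self.values) or len(self.positions) < 2:
            raise DataError("positions and values must have equal length >= 2")
        if not np.all(np.isfinite(self.positions)) or not np.all(np.isfinite(self.values)):
            raise DataError("positions and values must be finite")
        if np.any(np.diff(self.positions) <= 0):
            raise DataError("positions must be strictly increasing")
        if np.any(self.values < 0):
            raise DataError("dose values must be non-negative")
        if self.axis == "depth":
            if self.scan_depth is not None:
                raise DataError("a depth-axis curve must not carry a scan_depth")
        else:
            if self.scan_depth is None:
                raise DataError("a profile must carry a scan_depth")
            if self.scan_depth < 0:
                raise DataError("scan_depth must be >= 0")

    # -- convenience ---------------------------------------------------

    @property
    def is_profile(self) -> bool:
        return self.axis != "depth"

    @property
    def field_along_axis(self) -> float:
        """Field size (mm) along the scanned direction."""
        if self.axis == "crossline":
            return self.field_x
        if self.axis == "inline":
            return self.field_y
        raise ValueError("a depth curve has no lateral field width")

    @property
    def extent(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def value_at(self, position: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated value; positions outside the extent error."""
        pos = np.asarray(position, dtype=float)
        lo, hi = self.extent
        if np.any(pos < lo) or np.any(pos > hi):
            raise ValueError(f"position outside curve extent [{lo}, {hi}] mm")
        out = np.interp(pos, self.positions, self.values)
        return float(out) if np.isscalar(position) else out

    def with_data(self, positions: np.ndarray, values: np.ndarray, **meta) -> "ScanCurve":
        """Copy of this curve with new samples (and optional metadata changes)."""
        return replace(self, positions=np.asarray(positions, float),
                       values=np.asarray(values, float), **meta)


@dataclass
class DoseGrid:
    """Regular 2D or 3D dose array with physical geometry.

    ``origin`` and ``spacing`` are given per *array axis*, in the same
    order as ``values.shape`` (for a DICOM-derived 3D grid that order is
    z, y, x).  Spacing in mm, dose in Gy (or percent for normalized
    planes — the unit is the caller's contract, carried unchanged).
    """

    origin: tuple[float, ...]
    spacing: tuple[float, ...]
    values: np.ndarray
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = tuple(float(o) for o in self.origin)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.values.ndim not in (2, 3):
            raise DataError("dose grid must be 2D or 3D")
        if self.values.size == 0:
            raise DataError("dose grid must be non-empty")
        if len(self.origin) != self.values.ndim or len(self.spacing) != self.values.ndim:
            raise DataError("origin/spacing length must match array dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise DataError("grid spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise DataError("grid values must be finite")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one array axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.values.shape[axis])

    @property
    def bounds(self) -> list[tuple[float, float]]:
        """(min, max) voxel-center coordinate per axis."""
        return [(float(c[0]), float(c[-1])) for c in
                (self.coords(i) for i in range(self.ndim))]


@dataclass(frozen=True)
class PointDoseRecord:
    """One patient's TPS / VS / ion-chamber dose triplet (Gy)."""

    patient_id: str
    technique: str
    dose_tps: float
    dose_vs: float
    dose_ic: float

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ParseError(
                f"technique {self.technique!r} not in {TECHNIQUES} "
                f"(patient {self.patient_id})")
        for name in ("dose_tps", "dose_vs", "dose_ic"):
            d = getattr(self, name)
            if not np.isfinite(d) or d <= 0:
                raise DataError(f"{name} must be > 0 (patient {self.patient_id}, got {d})")


# ---------------------------------------------------------------------------
# scan tables
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ("curve_id", "axis", "energy_label", "field_x", "field_y",
                 "ssd", "scan_depth", "collimation", "source",
                 "position", "value")
_SCAN_NUMERIC = ("field_x", "field_y", "ssd", "scan_depth", "position", "value")


def read_scan_table(path: str | Path) -> list[ScanCurve]:
    """Read a scan-table CSV into a list of :class:`ScanCurve`.

    The dialect is comma-separated UTF-8 with ``#`` comment lines and a
    header row naming at least the columns
    ``curve_id, axis, energy_label, field_x, field_y, ssd, scan_depth,
    collimation, source, position, value``.  Rows with equal ``curve_id``
    form one curve; metadata is taken from the first row of each block.
    Curves stored with descending positions are sorted ascending (scanners
    sweep both directions) with a logged warning; duplicate positions are
    an error.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in _SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    for col in _SCAN_NUMERIC:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = coerced.isna() & ~blank
        if bad.any():
            # +2: header line and 1-based numbering
            row = int(df.index[bad][0]) + 2
            raise ParseError(f"{path.name}: non-numeric value in column "
                             f"'{col}' at data row {row}")
        df[col] = coerced

    curves: list[ScanCurve] = []
    for cid, block in df.groupby("curve_id", sort=False):
        pos = block["position"].to_numpy(dtype=float)
        val = block["value"].to_numpy(dtype=float)
        if len(pos) >= 2 and np.all(np.diff(pos) < 0):
            log.warning("curve %r stored with descending positions; sorting ascending", cid)
            pos, val = pos[::-1], val[::-1]
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        if np.any(np.diff(pos) == 0):
            raise DataError(f"curve {cid!r}: duplicate positions after sorting")
        first = block.iloc[0]
        depth = first["scan_depth"]
        try:
            curves.append(ScanCurve(
                axis=str(first["axis"]),
                positions=pos, values=val,
                energy_label=str(first["energy_label"]),
                field_x=float(first["field_x"]), field_y=float(first["field_y"]),
                ssd=float(first["ssd"]),
                scan_depth=None if pd.isna(depth) else float(depth),
                collimation=str(first["collimation"]),
                source=str(first["source"]),
            ))
        except DataError as exc:
            raise DataError(f"curve {cid!r}: {exc}") from exc
    return curves


def write_scan_table(curves: Sequence[ScanCurve], path: str | Path) -> Path:
    """Write curves in the dialect read by :func:`read_scan_table`.

    Numeric fields are rendered with 12 significant digits so a round
    trip preserves data to well under 1e-9 relative.
    """
    if not curves:
        raise ValueError("cannot write an empty curve collection")
    path = Path(path)
    rows = []
    for i, c in enumerate(curves):
        cid = f"c{i:04d}"
        for p, v in zip(c.positions, c.values):
            rows.append({
                "curve_id": cid, "axis": c.axis, "energy_label": c.energy_label,
                "field_x": c.field_x, "field_y": c.field_y, "ssd": c.ssd,
                "scan_depth": "" if c.scan_depth is None else c.scan_depth,
                "collimation": c.collimation, "source": c.source,
                "position": p, "value": v,
            })
    frame = pd.DataFrame(rows, columns=list(_SCAN_COLUMNS))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# beamcheck scan table\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# dose grids
# ---------------------------------------------------------------------------


def read_dose_grid(path: str | Path, format: str = "text_grid") -> DoseGrid:
    """Read a dose grid from a headered text matrix or a DICOM RT Dose file.

    The text format has ``#`` comments, then ``origin:`` and ``spacing:``
    header lines (one number per array axis, mm), an optional ``shape:``
    line (required for 3D), an optional ``frame:`` label, and then the
    matrix body, one row per line (3D: ``shape[0]*shape[1]`` lines of
    ``shape[2]`` numbers).  DICOM pixel data are scaled by the stored
    dose-grid scaling factor into Gy.
    """
    if format == "dicom_rt_dose":
        return _read_dicom_rt_dose(path)
    if format != "text_grid":
        raise ValueError(f"unknown dose-grid format {format!r}")
    path = Path(path)
    origin = spacing = shape = None
    frame_label = ""
    body: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("origin:"):
                origin = tuple(float(t) for t in line.split(":", 1)[1].split())
            elif line.startswith("spacing:"):
                spacing = tuple(float(t) for t in line.split(":", 1)[1].split())
            elif line.startswith("shape:"):
                shape = tuple(int(t) for t in line.split(":", 1)[1].split())
            elif line.startswith("frame:"):
                frame_label = line.split(":", 1)[1].strip()
            else:
                try:
                    body.append([float(t) for t in line.replace(",", " ").split()])
                except ValueError as exc:
                    raise ParseError(f"{path.name}: non-numeric matrix entry "
                                     f"at line {lineno}") from exc
    if origin is None or spacing is None:
        raise FormatError(f"{path.name}: missing origin/spacing header")
    widths = {len(r) for r in body}
    if len(widths) != 1:
        raise FormatError(f"{path.name}: ragged matrix rows (widths {sorted(widths)})")
    arr = np.asarray(body, dtype=float)
    if shape is not None and len(shape) == 3:
        if arr.shape[0] != shape[0] * shape[1] or arr.shape[1] != shape[2]:
            raise FormatError(f"{path.name}: body does not match declared shape {shape}")
        arr = arr.reshape(shape)
    return DoseGrid(origin=origin, spacing=spacing, values=arr, frame_label=frame_label)


def write_dose_grid(grid: DoseGrid, path: str | Path) -> Path:
    """Write the text-matrix dialect read by :func:`read_dose_grid`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# beamcheck dose grid\n")
        if grid.frame_label:
            fh.write(f"frame: {grid.frame_label}\n")
        fh.write("origin: " + " ".join(_FLOAT_FMT % o for o in grid.origin) + "\n")
        fh.write("spacing: " + " ".join(_FLOAT_FMT % s for s in grid.spacing) + "\n")
        if grid.ndim == 3:
            fh.write("shape: " + " ".join(str(n) for n in grid.values.shape) + "\n")
            flat = grid.values.reshape(-1, grid.values.shape[-1])
        else:
            flat = grid.values
        for row in flat:
            fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")
    return path


def _read_dicom_rt_dose(path: str | Path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{Path(path).name}: not an RT Dose object "
                          f"(Modality={getattr(ds, 'Modality', None)!r})")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling
    row_sp, col_sp = (float(x) for x in ds.PixelSpacing)
    ipp = [float(x) for x in ds.ImagePositionPatient]
    if arr.ndim == 3:
        offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
        dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
        return DoseGrid(origin=(ipp[2], ipp[1], ipp[0]),
                        spacing=(dz, row_sp, col_sp), values=arr,
                        frame_label="dicom")
    return DoseGrid(origin=(ipp[1], ipp[0]), spacing=(row_sp, col_sp),
                    values=arr, frame_label="dicom")


# ---------------------------------------------------------------------------
# point doses
# ---------------------------------------------------------------------------

_POINT_COLUMNS = ("patient_id", "technique", "dose_tps", "dose_vs", "dose_ic")


def read_point_doses(path: str | Path) -> list[PointDoseRecord]:
    """Read a point-dose CSV (columns patient_id, technique, dose_tps, dose_vs, dose_ic)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"patient_id": str, "technique": str})
    missing = [c for c in _POINT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(PointDoseRecord(
            patient_id=str(row["patient_id"]), technique=str(row["technique"]),
            dose_tps=float(row["dose_tps"]), dose_vs=float(row["dose_vs"]),
            dose_ic=float(row["dose_ic"])))
    return records


def write_point_doses(records: Sequence[PointDoseRecord], path: str | Path) -> Path:
    if not records:
        raise ValueError("cannot write an empty point-dose collection")
    path = Path(path)
    frame = pd.DataFrame([{
        "patient_id": r.patient_id, "technique": r.technique,
        "dose_tps": r.dose_tps, "dose_vs": r.dose_vs, "dose_ic": r.dose_ic,
    } for r in records], columns=list(_POINT_COLUMNS))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# beamcheck point doses\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path
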