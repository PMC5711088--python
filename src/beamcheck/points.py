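"""Chamber-ROI dose extraction and point-dose ratio statistics.

The patient-specific point-dose check compares three numbers per
patient: the treatment planning system (TPS) dose and the verification
system (VS) dose — each read as the mean over a cylindrical region of
interest matching the ion chamber's sensitive volume — and the measured
ion-chamber (IC) dose.  The per-patient ratios TPS/IC, VS/IC and TPS/VS
are tabulated and summarized as mean ± sd for all cases together and for
the VMAT and IMRT subgroups separately.

The default chamber geometry is a small cylindrical thimble (2 mm
radius, 3.6 mm length, comparable to a CC04): an assumption, since
chamber dimensions are configurable per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from beamcheck.errors import DataError
from beamcheck.io import DoseGrid, PointDoseRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChamberROI:
    """Cylindrical ion-chamber region of interest.

    ``center`` in grid coordinates (mm, array-axis order), ``radius`` and
    ``length`` in mm, ``axis_direction`` a unit vector along the cylinder
    axis (default along array axis 0).
    """

    center: tuple[float, float, float]
    radius: float = 2.0
    length: float = 3.6
    axis_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be > 0")
        u = np.asarray(self.axis_direction, dtype=float)
        norm = float(np.linalg.norm(u))
        if norm == 0:
            raise ValueError("axis_direction must be non-zero")
        object.__setattr__(self, "axis_direction", tuple(u / norm))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


def chamber_roi_mean(grid: DoseGrid, roi: ChamberROI) -> float:
    """Mean dose (Gy) over voxels whose centers lie inside the cylinder.

    Voxel-center inclusion, no partial-volume weighting.  The ROI's
    bounding sphere must lie inside the grid extent; an ROI that
    includes no voxel centers raises a data error suggesting a finer
    grid.
    """
    if grid.ndim != 3:
        raise ValueError("chamber_roi_mean requires a 3D dose grid")
    half_diag = float(np.hypot(roi.radius, roi.length / 2.0))
    for ax, (lo, hi) in enumerate(grid.bounds):
        if roi.center[ax] - half_diag < lo - 1e-9 or roi.center[ax] + half_diag > hi + 1e-9:
            raise ValueError(
                f"ROI extends outside the grid along axis {ax} "
                f"(center {roi.center[ax]:g} ± {half_diag:g} mm vs [{lo:g}, {hi:g}] mm)")
    axes = [grid.coords(i) - roi.center[i] for i in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    u = np.asarray(roi.axis_direction)
    axial = mesh[0] * u[0] + mesh[1] * u[1] + mesh[2] * u[2]
    r2 = (mesh[0] - axial * u[0]) ** 2 + (mesh[1] - axial * u[1]) ** 2 \
        + (mesh[2] - axial * u[2]) ** 2
    inside = (np.abs(axial) <= roi.length / 2.0 + 1e-12) & \
             (r2 <= roi.radius ** 2 + 1e-12)
    if not inside.any():
        raise DataError("no voxel centers inside the chamber ROI; "
                        "use a finer dose grid")
    return float(np.mean(grid.values[inside]))


@dataclass(frozen=True)
class RatioSummary:
    """Mean ± sd (percent) of the three dose ratios for one patient group."""

    group_label: str
    n: int
    mean_tps_ic: float
    sd_tps_ic: float
    mean_vs_ic: float
    sd_vs_ic: float
    mean_tps_vs: float
    sd_tps_vs: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("a ratio summary requires at least one record")
        if min(self.sd_tps_ic, self.sd_vs_ic, self.sd_tps_vs) < 0:
            raise DataError("sds must be >= 0")


def ratio_table(records: Sequence[PointDoseRecord]) -> pd.DataFrame:
    """Per-patient dose ratios in percent: 100·TPS/IC, 100·VS/IC, 100·TPS/VS."""
    if not records:
        raise ValueError("records must be non-empty")
    return pd.DataFrame([{
        "patient_id": r.patient_id,
        "technique": r.technique,
        "tps_ic": 100.0 * r.dose_tps / r.dose_ic,
        "vs_ic": 100.0 * r.dose_vs / r.dose_ic,
        "tps_vs": 100.0 * r.dose_tps / r.dose_vs,
    } for r in records])


def aggregate_ratios(records: Sequence[PointDoseRecord]) -> list[RatioSummary]:
    """Mean ± sd ratio summaries for Total, VMAT-only and IMRT-only groups.

    Sample (n−1) standard deviation; single-record groups report sd 0.
    Groups with no members are omitted with a logged notice.
    """
    table = ratio_table(records)
    out: list[RatioSummary] = []
    groups = [("Total", table),
              ("VMAT", table[table["technique"] == "VMAT"]),
              ("IMRT", table[table["technique"] == "IMRT"])]
    for label, sub in groups:
        if len(sub) == 0:
            log.info("no %s cases in the cohort; group omitted", label)
            continue
        def stat(col: str) -> tuple[float, float]:
            x = sub[col].to_numpy()
            return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        m1, s1 = stat("tps_ic")
        m2, s2 = stat("vs_ic")
        m3, s3 = stat("tps_vs")
        out.append(RatioSummary(group_label=f"{label} (n={len(sub)})", n=len(sub),
                                mean_tps_ic=m1, sd_tps_ic=s1,
                                mean_vs_ic=m2, sd_vs_ic=s2,
                                mean_tps_vs=m3, sd_tps_vs=s3))
    return out
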