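"""PDD and profile comparison metrics.

The analysis pipeline for curve comparison is:

1. resample every curve to a common 1 mm grid (:func:`resample`);
2. renormalize PDDs to their maximum (Dmax = 100,
   :func:`normalize_pdd`) and profiles to the central axis
   (CAX = 100, :func:`normalize_profile`);
3. for PDDs, average the per-point difference from Dmax down to 25 cm
   depth (:func:`mean_pdd_error`);
4. for profiles, segment into in-field / penumbra / tail regions
   (:func:`segment_profile`) and compute per-region statistics
   (:func:`infield_difference`, :func:`tail_difference`; the penumbral
   distance-to-agreement pass rates live in :mod:`beamcheck.gamma`).

Region conventions: the in-field region is the central 80% of the
geometric field size projected to the scan depth; each penumbra is the
interval between the 80% and 20% dose levels; each tail runs from the
20% level a further 15 mm away from the field.  All intervals are
closed — boundary grid points are included.

Differences are signed, ``test - reference``, in percentage points of
the normalization value (Dmax or CAX = 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from beamcheck.errors import DataError
from beamcheck.io import ScanCurve

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the commissioning analysis.

    Defaults mirror standard clinical practice: curves resampled at 1 mm,
    PDD error window ending at 250 mm depth, in-field = central 80% of
    the projected field, penumbra bounded by the 20%/80% levels, 15 mm
    tails, 2%/2 mm penumbral criteria, 1.5%/1.5 mm small-field in-field
    criteria, 3%/3 mm planar gamma with a 90% clinical pass threshold.
    """

    resample_step: float = 1.0            # mm
    pdd_depth_end: float = 250.0          # mm
    infield_fraction: float = 0.8
    edge_levels: tuple[float, float] = (20.0, 80.0)   # percent of CAX
    tail_extension: float = 15.0          # mm
    penumbra_criteria: tuple[float, float] = (2.0, 2.0)          # %, mm
    smallfield_infield_criteria: tuple[float, float] = (1.5, 1.5)  # %, mm
    planar_gamma_criteria: tuple[float, float] = (3.0, 3.0)      # %, mm
    planar_pass_threshold: float = 90.0   # percent of pixels passing
    nominal_ssd: float = 1000.0           # mm
    smallfield_max_width: float = 20.0    # mm; MLC fields at or below route to DTA path

    def __post_init__(self) -> None:
        for name in ("resample_step", "pdd_depth_end", "tail_extension",
                     "planar_pass_threshold", "nominal_ssd", "smallfield_max_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.infield_fraction < 1:
            raise ValueError("infield_fraction must be in (0, 1)")
        for pair_name in ("penumbra_criteria", "smallfield_infield_criteria",
                          "planar_gamma_criteria"):
            pair = tuple(getattr(self, pair_name))
            if len(pair) != 2 or any(t <= 0 for t in pair):
                raise ValueError(f"{pair_name} must be two positive numbers")
            setattr(self, pair_name, pair)
        lo, hi = self.edge_levels
        if not (0 < lo < hi < 100):
            raise ValueError("edge_levels must satisfy 0 < low < high < 100")
        self.edge_levels = (float(lo), float(hi))

    # -- YAML round trip ----------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        import yaml

        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in data.items():
            if isinstance(v, list):
                data[k] = tuple(v)
        return cls(**data)


@dataclass
class ProfileRegions:
    """In-field, penumbra and tail intervals (mm) of one profile.

    Intervals are closed ``(low, high)`` pairs.  For fields so small that
    the 80% level falls inside the central-80% window (physically the
    whole field is gradient), ``overlaps_infield`` is set instead of
    raising; strict validation rejects such regions.
    """

    infield: tuple[float, float]
    penumbra_left: tuple[float, float]
    penumbra_right: tuple[float, float]
    tail_left: tuple[float, float]
    tail_right: tuple[float, float]
    projected_width: float
    edge_levels: tuple[float, float] = (20.0, 80.0)
    tail_extension: float = 15.0
    overlaps_infield: bool = False

    def __post_init__(self) -> None:
        for name in ("infield", "penumbra_left", "penumbra_right",
                     "tail_left", "tail_right"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise DataError(f"{name} interval reversed: ({lo}, {hi})")
        for name in ("tail_left", "tail_right"):
            lo, hi = getattr(self, name)
            if abs((hi - lo) - self.tail_extension) > 1e-6:
                raise DataError(f"{name} must span the tail extension "
                                f"({self.tail_extension} mm)")
        self.overlaps_infield = bool(
            self.penumbra_left[1] > self.infield[0] + 1e-9
            or self.penumbra_right[0] < self.infield[1] - 1e-9)

    def validate_strict(self) -> None:
        """Require the penumbrae to lie entirely outside the in-field interval."""
        if self.overlaps_infield:
            raise DataError("penumbra overlaps the in-field region "
                            "(field too small for a flat core)")


@dataclass(frozen=True)
class CurveErrorSummary:
    """Mean +/- sd of pooled per-point differences, in percentage points."""

    field_label: str
    mean_diff: float
    sd_diff: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise DataError("summary requires at least one point")
        if self.sd_diff < 0:
            raise DataError("sd must be >= 0")


# ---------------------------------------------------------------------------
# resampling and normalization
# ---------------------------------------------------------------------------


def resample(curve: ScanCurve, step: float) -> ScanCurve:
    """Resample a curve onto an arithmetic grid of the given step (mm).

    The grid starts at the curve's first position and covers its extent;
    when the extent is an exact multiple of ``step`` both endpoints are
    preserved.  Values are linearly interpolated.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    lo, hi = curve.extent
    if step > hi - lo:
        raise ValueError(f"step {step} mm exceeds curve extent {hi - lo} mm")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    positions = lo + step * np.arange(n)
    values = np.interp(positions, curve.positions, curve.values)
    return curve.with_data(positions, values)


def normalize_pdd(curve: ScanCurve) -> tuple[ScanCurve, float]:
    """Renormalize a PDD so its maximum is 100; return (curve, dmax depth).

    Ties in the maximum are broken toward the shallowest depth.
    """
    if curve.axis != "depth":
        raise ValueError("normalize_pdd requires a depth-axis curve")
    imax = int(np.argmax(curve.values))  # argmax returns the first (shallowest) tie
    peak = curve.values[imax]
    if peak <= 0:
        raise DataError("PDD maximum must be positive")
    return curve.with_data(curve.positions, curve.values * (100.0 / peak)), \
        float(curve.positions[imax])


def normalize_profile(curve: ScanCurve) -> ScanCurve:
    """Scale a lateral profile so the interpolated central-axis value is 100."""
    if curve.axis == "depth":
        raise ValueError("normalize_profile requires a lateral profile")
    lo, hi = curve.extent
    if not lo <= 0 <= hi:
        raise ValueError("central axis (position 0) outside profile extent")
    cax = float(np.interp(0.0, curve.positions, curve.values))
    if cax <= 0:
        raise DataError("central-axis value must be positive")
    return curve.with_data(curve.positions, curve.values * (100.0 / cax))


# ---------------------------------------------------------------------------
# PDD comparison
# ---------------------------------------------------------------------------


def mean_pdd_error(reference: ScanCurve, test: ScanCurve,
                   config: AnalysisConfig | None = None) -> CurveErrorSummary:
    """Average signed PDD difference from the reference Dmax down to 25 cm.

    Both curves must already be renormalized to Dmax = 100 and resampled
    to the analysis grid.  The per-point difference ``test - reference``
    (percentage points of Dmax) is averaged over reference grid points in
    ``[dmax_depth(reference), pdd_depth_end]``; the window start uses the
    *reference* curve's Dmax depth.
    """
    config = config or AnalysisConfig()
    if reference.axis != "depth" or test.axis != "depth":
        raise ValueError("mean_pdd_error requires depth-axis curves")
    dmax_depth = float(reference.positions[int(np.argmax(reference.values))])
    end = config.pdd_depth_end
    mask = (reference.positions >= dmax_depth - 1e-9) & \
           (reference.positions <= end + 1e-9)
    window = reference.positions[mask]
    if window.size == 0 or window[-1] < end - config.resample_step:
        raise DataError(
            f"reference PDD does not cover the analysis window "
            f"[{dmax_depth:.1f}, {end:.1f}] mm (covers to {reference.positions[-1]:.1f})")
    t_lo, t_hi = test.extent
    if t_lo > window[0] + 1e-9 or t_hi < window[-1] - 1e-9:
        raise DataError(
            f"test PDD does not cover the analysis window "
            f"[{window[0]:.1f}, {window[-1]:.1f}] mm (covers [{t_lo:.1f}, {t_hi:.1f}])")
    diffs = np.interp(window, test.positions, test.values) - reference.values[mask]
    label = field_label(reference)
    return CurveErrorSummary(field_label=label, mean_diff=float(np.mean(diffs)),
                             sd_diff=_sample_sd(diffs), n_points=int(diffs.size))


def field_label(curve: ScanCurve) -> str:
    """Human-readable field-size label in cm, e.g. ``"10x10"``."""
    return f"{curve.field_x / 10:g}x{curve.field_y / 10:g}"


def _sample_sd(x: np.ndarray) -> float:
    """Sample (n-1) standard deviation; 0.0 for a single point."""
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


# ---------------------------------------------------------------------------
# profile geometry
# ---------------------------------------------------------------------------


def projected_field_width(width_nominal: float, ssd: float, depth: float) -> float:
    """Geometric field width projected from the nominal SSD plane to depth.

    Similar triangles from the source: ``width * (ssd + depth) / ssd``.
    """
    if width_nominal <= 0 or ssd <= 0:
        raise ValueError("width and ssd must be > 0")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return width_nominal * (ssd + depth) / ssd


def _level_crossings(positions: np.ndarray, values: np.ndarray,
                     level: float) -> np.ndarray:
    """All positions where the piecewise-linear curve crosses ``level``."""
    d = values - level
    out = list(positions[d == 0])
    sign_change = d[:-1] * d[1:] < 0
    idx = np.nonzero(sign_change)[0]
    for i in idx:
        frac = d[i] / (d[i] - d[i + 1])
        out.append(positions[i] + frac * (positions[i + 1] - positions[i]))
    return np.sort(np.asarray(out, dtype=float))


def find_edge_positions(profile: ScanCurve, level: float) -> tuple[float, float]:
    """Left and right positions (mm) where a normalized profile crosses ``level``.

    The profile must be normalized to CAX = 100.  When noise produces
    multiple crossings on a side, the crossing nearest that side's 50%
    crossing is used.
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100) percent")
    pos, val = profile.positions, profile.values

    def side_crossing(lvl: float, side: str, anchor: float | None) -> float:
        crossings = _level_crossings(pos, val, lvl)
        cand = crossings[crossings < 0] if side == "left" else crossings[crossings > 0]
        if cand.size == 0:
            raise DataError(f"no {lvl:g}% crossing on the {side} side of the profile")
        if anchor is None:  # the 50% anchor itself: take the crossing nearest the CAX
            return float(cand[np.argmax(cand)] if side == "left" else cand[np.argmin(cand)])
        return float(cand[np.argmin(np.abs(cand - anchor))])

    left50 = side_crossing(50.0, "left", None)
    right50 = side_crossing(50.0, "right", None)
    return (side_crossing(level, "left", left50),
            side_crossing(level, "right", right50))


def segment_profile(profile: ScanCurve,
                    config: AnalysisConfig | None = None) -> ProfileRegions:
    """Split a normalized, resampled profile into analysis regions.

    The in-field interval is the central ``infield_fraction`` of the
    geometric field width projected to the scan depth, centered on the
    beam axis.  Each penumbra spans the 80%-to-20% dose falloff found by
    :func:`find_edge_positions`; each tail extends a further
    ``tail_extension`` mm outward from the 20% position.
    """
    config = config or AnalysisConfig()
    if not profile.is_profile:
        raise ValueError("segment_profile requires a lateral profile")
    width = projected_field_width(profile.field_along_axis, profile.ssd,
                                  profile.scan_depth)
    half = 0.5 * config.infield_fraction * width
    low, high = config.edge_levels
    l_hi, r_hi = find_edge_positions(profile, high)
    l_lo, r_lo = find_edge_positions(profile, low)
    lo_pos, hi_pos = profile.extent
    ext = config.tail_extension
    if l_lo - ext < lo_pos - 1e-9 or r_lo + ext > hi_pos + 1e-9:
        raise DataError(
            f"profile extent [{lo_pos:.1f}, {hi_pos:.1f}] mm too short for "
            f"{ext:g} mm tails beyond the {low:g}% positions "
            f"({l_lo:.1f} / {r_lo:.1f} mm)")
    return ProfileRegions(
        infield=(-half, half),
        penumbra_left=(l_lo, l_hi), penumbra_right=(r_hi, r_lo),
        tail_left=(l_lo - ext, l_lo), tail_right=(r_lo, r_lo + ext),
        projected_width=width, edge_levels=(low, high), tail_extension=ext)


# ---------------------------------------------------------------------------
# region difference metrics
# ---------------------------------------------------------------------------


def _region_diffs(reference: ScanCurve, test: ScanCurve,
                  intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(reference.positions.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (reference.positions >= lo - 1e-9) & (reference.positions <= hi + 1e-9)
    pts = reference.positions[mask]
    if pts.size == 0:
        raise DataError("no grid points inside the requested region")
    t_lo, t_hi = test.extent
    if pts[0] < t_lo - 1e-9 or pts[-1] > t_hi + 1e-9:
        raise DataError("test curve does not cover the requested region")
    return np.interp(pts, test.positions, test.values) - reference.values[mask]


def infield_difference(reference: ScanCurve, test: ScanCurve,
                       regions: ProfileRegions) -> np.ndarray:
    """Signed per-point differences (test - reference) inside the in-field interval.

    Returns the raw differences; callers pool them across depths per
    field size before computing the mean +/- sd in-field error.
    """
    return _region_diffs(reference, test, [regions.infield])


def tail_difference(reference: ScanCurve, test: ScanCurve,
                    regions: ProfileRegions) -> np.ndarray:
    """Signed per-point differences over both tail intervals."""
    return _region_diffs(reference, test, [regions.tail_left, regions.tail_right])


def pool_differences(diff_arrays: Sequence[np.ndarray], label: str) -> CurveErrorSummary:
    """Pool per-profile difference arrays and summarize as mean +/- sample sd."""
    if not diff_arrays:
        raise DataError("nothing to pool")
    pooled = np.concatenate([np.asarray(d, float) for d in diff_arrays])
    return CurveErrorSummary(field_label=label, mean_diff=float(np.mean(pooled)),
                             sd_diff=_sample_sd(pooled), n_points=int(pooled.size))
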