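"""Distance-to-agreement and gamma-index comparison engines.

Two point-acceptance tests are provided for comparing a test dose
distribution against a reference:

* the *composite* criterion (x%/y mm): a point passes when its dose
  difference is within ``dose_tol`` OR its distance-to-agreement (DTA —
  the distance to the nearest reference location with the same dose) is
  within ``dist_tol``;
* the *gamma index*: per evaluated point, the minimum over reference
  locations r of ``sqrt(|Δr|²/dist_tol² + ΔD²/dose_tol²)``; the point
  passes when gamma ≤ 1.

Both operate on :class:`~beamcheck.io.ScanCurve` (1D) and
:class:`~beamcheck.io.DoseGrid` (2D, and toy-sized 3D) inputs.  The
reference distribution is linearly subsampled to at most one third of
``dist_tol`` before the search; the search is restricted to a radius of
three times ``dist_tol`` and gamma values that would exceed the
radius-limited bound are capped at that bound (which cannot change the
pass/fail outcome, since the cap is 3).

Dose-difference normalization (``Criteria.norm_mode``):

``global_cax``
    differences are percentage points of the normalization value 100 —
    appropriate for profiles normalized to CAX = 100;
``global_max``
    percent of the reference distribution's maximum (planar convention);
``local``
    percent of the local reference dose.

:func:`gamma_map_bruteforce` recomputes gamma by an exhaustive scan over
every reference sample — an independent code path used to validate the
radius-limited tree search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from beamcheck.errors import DataError
from beamcheck.io import DoseGrid, ScanCurve

NORM_MODES = ("global_cax", "global_max", "local")


@dataclass(frozen=True)
class Criteria:
    """Agreement criteria: dose tolerance (%), distance tolerance (mm)."""

    dose_tol: float
    dist_tol: float
    norm_mode: str = "global_cax"

    def __post_init__(self) -> None:
        if self.dose_tol <= 0 or self.dist_tol <= 0:
            raise ValueError("dose_tol and dist_tol must be > 0")
        if self.norm_mode not in NORM_MODES:
            raise ValueError(f"norm_mode must be one of {NORM_MODES}")


@dataclass
class GammaResult:
    """Per-point gamma values and the derived pass fraction.

    ``gamma_values`` is shaped like the evaluated distribution, with NaN
    at points excluded by the low-dose cutoff.  ``n_capped`` counts
    points whose gamma hit the radius-limited search bound ``cap``.
    """

    gamma_values: np.ndarray
    pass_fraction: float
    criteria: Criteria
    n_evaluated: int
    n_capped: int = 0
    cap: float = math.inf

    def __post_init__(self) -> None:
        finite = self.gamma_values[np.isfinite(self.gamma_values)]
        if np.any(finite < 0):
            raise DataError("gamma values must be >= 0")


# ---------------------------------------------------------------------------
# fine subsampling of the reference
# ---------------------------------------------------------------------------


def _fine_curve(curve: ScanCurve, max_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly subsample a curve so spacing <= max_spacing, keeping its nodes."""
    pos = curve.positions
    out = [pos[:1]]
    for p0, p1 in zip(pos[:-1], pos[1:]):
        n = max(1, int(math.ceil((p1 - p0) / max_spacing - 1e-12)))
        out.append(p0 + (p1 - p0) * np.arange(1, n + 1) / n)
    fine = np.concatenate(out)
    return fine, np.interp(fine, pos, curve.values)


def _fine_grid(grid: DoseGrid, max_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Multilinearly subsample a grid; returns (points (N, d), values (N,))."""
    from scipy.interpolate import RegularGridInterpolator

    axes = []
    for i in range(grid.ndim):
        factor = max(1, int(math.ceil(grid.spacing[i] / max_spacing - 1e-12)))
        n = (grid.values.shape[i] - 1) * factor + 1
        axes.append(grid.origin[i] + (grid.spacing[i] / factor) * np.arange(n))
    interp = RegularGridInterpolator([grid.coords(i) for i in range(grid.ndim)],
                                     grid.values, method="linear")
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    return points, interp(points)


def _eval_points(dist: ScanCurve | DoseGrid) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dist, ScanCurve):
        return dist.positions[:, None], dist.values
    mesh = np.meshgrid(*[dist.coords(i) for i in range(dist.ndim)], indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1), dist.values.ravel()


def _ref_samples(dist: ScanCurve | DoseGrid,
                 max_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dist, ScanCurve):
        fine, vals = _fine_curve(dist, max_spacing)
        return fine[:, None], vals
    return _fine_grid(dist, max_spacing)


def _bounds(dist: ScanCurve | DoseGrid) -> list[tuple[float, float]]:
    if isinstance(dist, ScanCurve):
        return [dist.extent]
    return dist.bounds


def _check_overlap(reference, evaluated) -> None:
    for (rlo, rhi), (elo, ehi) in zip(_bounds(reference), _bounds(evaluated)):
        if ehi < rlo or elo > rhi:
            raise DataError("reference and evaluated distributions are "
                            "spatially disjoint")


def _denominators(criteria: Criteria, ref_values: np.ndarray) -> np.ndarray | float:
    """Absolute dose-difference scale per reference sample."""
    if criteria.norm_mode == "global_cax":
        return criteria.dose_tol  # values already percent of 100
    if criteria.norm_mode == "global_max":
        return criteria.dose_tol / 100.0 * float(np.max(ref_values))
    denom = criteria.dose_tol / 100.0 * np.abs(ref_values)
    return np.where(denom > 0, denom, np.inf)


def _cutoff_mask(eval_values: np.ndarray, ref_values: np.ndarray,
                 criteria: Criteria, low_dose_cutoff: float | None) -> np.ndarray:
    """Evaluated points retained under the cutoff (percent of reference max)."""
    if low_dose_cutoff is None:
        return np.ones(eval_values.shape, dtype=bool)
    norm = 100.0 if criteria.norm_mode == "global_cax" else float(np.max(ref_values))
    return eval_values >= low_dose_cutoff / 100.0 * norm


# ---------------------------------------------------------------------------
# DTA
# ---------------------------------------------------------------------------


def dta_mm(test_position, test_value: float,
           reference: ScanCurve | DoseGrid,
           search_cap: float | None = None) -> float:
    """Distance (mm) to the nearest reference location with the test's dose.

    The reference is subsampled (0.1 mm for curves; fine bilinear grid
    for planes) and the dose level set ``{r : D_ref(r) = test_value}`` is
    located by linear interpolation between samples.  Returns ``inf``
    when no such location exists within ``search_cap`` (no cap when
    ``None``).
    """
    if isinstance(reference, ScanCurve):
        return _dta_curve(float(np.ravel(test_position)[0]), test_value,
                          reference.positions, reference.values, search_cap)
    return _dta_grid(np.asarray(test_position, float), test_value,
                     reference, search_cap)


def _dta_curve(p: float, v: float, pos: np.ndarray, val: np.ndarray,
               cap: float | None) -> float:
    if cap is not None:
        lo, hi = p - cap, p + cap
        mask = (pos >= lo) & (pos <= hi)
        # keep bracketing neighbors so interval crossings at the window edge count
        idx = np.nonzero(mask)[0]
        start = max(0, (idx[0] if idx.size else np.searchsorted(pos, lo)) - 1)
        stop = min(len(pos), (idx[-1] + 2) if idx.size else np.searchsorted(pos, hi) + 1)
        pos, val = pos[start:stop], val[start:stop]
        if pos.size == 0:
            return math.inf
    d = val - v
    best = math.inf
    exact = pos[d == 0]
    if exact.size:
        best = float(np.min(np.abs(exact - p)))
    sign_change = np.nonzero(d[:-1] * d[1:] < 0)[0]
    for i in sign_change:
        frac = d[i] / (d[i] - d[i + 1])
        x = pos[i] + frac * (pos[i + 1] - pos[i])
        best = min(best, abs(x - p))
    if cap is not None and best > cap:
        return math.inf
    return best


def _dta_grid(p: np.ndarray, v: float, grid: DoseGrid,
              cap: float | None, fine_step: float = 0.1) -> float:
    if grid.ndim != 2:
        raise ValueError("grid DTA is implemented for 2D planes")
    from scipy.interpolate import RegularGridInterpolator

    bounds = grid.bounds
    if cap is not None:
        window = [(max(b[0], p[i] - cap), min(b[1], p[i] + cap)) for i, b in enumerate(bounds)]
    else:
        window = bounds
    axes = []
    for lo, hi in window:
        if hi <= lo:
            return math.inf
        n = max(2, int(math.ceil((hi - lo) / fine_step)) + 1)
        n = min(n, 2001)  # resolution floor for very large windows
        axes.append(np.linspace(lo, hi, n))
    interp = RegularGridInterpolator([grid.coords(i) for i in range(2)],
                                     grid.values, method="linear")
    mesh = np.meshgrid(*axes, indexing="ij")
    vals = interp(np.stack([m.ravel() for m in mesh], axis=-1)).reshape(mesh[0].shape)
    d = vals - v
    best = math.inf
    ii, jj = np.nonzero(d == 0)
    if ii.size:
        best = float(np.min(np.hypot(axes[0][ii] - p[0], axes[1][jj] - p[1])))
    # zero crossings along grid-line segments: bilinear is linear on them,
    # so the interpolated crossing point is exact on the fine lattice
    for axis in (0, 1):
        a = d if axis == 1 else d.T
        x_along = axes[1] if axis == 1 else axes[0]
        x_across = axes[0] if axis == 1 else axes[1]
        change = a[:, :-1] * a[:, 1:] < 0
        rows, cols = np.nonzero(change)
        if rows.size:
            frac = a[rows, cols] / (a[rows, cols] - a[rows, cols + 1])
            along = x_along[cols] + frac * (x_along[cols + 1] - x_along[cols])
            across = x_across[rows]
            if axis == 1:
                dist = np.hypot(across - p[0], along - p[1])
            else:
                dist = np.hypot(along - p[0], across - p[1])
            best = min(best, float(np.min(dist)))
    if cap is not None and best > cap:
        return math.inf
    return best


# ---------------------------------------------------------------------------
# composite pass rate on curves
# ---------------------------------------------------------------------------


def composite_pass_rate(reference: ScanCurve, test: ScanCurve,
                        region: tuple[float, float] | Sequence[tuple[float, float]],
                        criteria: Criteria, method: str = "composite",
                        fine_step: float = 0.1) -> float:
    """Fraction of test grid points in ``region`` passing the point test.

    Both curves must be normalized (CAX = 100) and resampled.  With
    ``method="composite"`` a point passes when its dose difference is
    within ``dose_tol`` (percentage points under ``global_cax``) or its
    DTA is within ``dist_tol``; with ``method="gamma"`` when its gamma
    index is ≤ 1.  ``region`` is one closed interval or a sequence of
    them (e.g. both penumbrae).
    """
    intervals = [region] if np.isscalar(region[0]) else list(region)
    mask = np.zeros(test.positions.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (test.positions >= lo - 1e-9) & (test.positions <= hi + 1e-9)
    if not mask.any():
        raise DataError("no grid points inside the requested region")
    pts, vals = test.positions[mask], test.values[mask]

    if method == "gamma":
        result = gamma_map(reference, test, criteria)
        return float(np.mean(result.gamma_values[mask] <= 1.0))
    if method != "composite":
        raise ValueError("method must be 'composite' or 'gamma'")

    ref_at = np.interp(pts, reference.positions, reference.values)
    if criteria.norm_mode == "local":
        scale = criteria.dose_tol / 100.0 * np.abs(ref_at)
        dose_ok = np.abs(vals - ref_at) <= np.where(scale > 0, scale, np.inf)
    elif criteria.norm_mode == "global_max":
        dose_ok = np.abs(vals - ref_at) <= \
            criteria.dose_tol / 100.0 * float(np.max(reference.values))
    else:  # global_cax: values are already percent of 100
        dose_ok = np.abs(vals - ref_at) <= criteria.dose_tol
    fine_pos, fine_val = _fine_curve(reference, fine_step)
    cap = 3.0 * criteria.dist_tol
    passed = 0
    for p, v, ok in zip(pts, vals, dose_ok):
        if ok or _dta_curve(p, v, fine_pos, fine_val, cap) <= criteria.dist_tol:
            passed += 1
    return passed / pts.size


# ---------------------------------------------------------------------------
# gamma engine
# ---------------------------------------------------------------------------


def gamma_map(reference: ScanCurve | DoseGrid,
              evaluated: ScanCurve | DoseGrid,
              criteria: Criteria,
              low_dose_cutoff: float | None = None,
              search_radius: float | None = None,
              subsample: float | None = None) -> GammaResult:
    """Gamma index of every evaluated point against the reference.

    The reference is linearly subsampled to spacing ``subsample``
    (default ``dist_tol / 3``) and searched within ``search_radius``
    (default ``3 * dist_tol``) of each evaluated point using a k-d tree.
    Gamma values above the radius-limited bound
    ``search_radius / dist_tol`` are reported as that bound and counted
    in ``n_capped``; the cap (3 by default) cannot change pass/fail.
    ``low_dose_cutoff`` (percent of the reference maximum) excludes
    low-dose evaluated points from the statistics.
    """
    _check_overlap(reference, evaluated)
    radius = 3.0 * criteria.dist_tol if search_radius is None else search_radius
    sub = criteria.dist_tol / 3.0 if subsample is None else subsample
    cap = radius / criteria.dist_tol

    ref_pos, ref_val = _ref_samples(reference, sub)
    ev_pos, ev_val = _eval_points(evaluated)
    keep = _cutoff_mask(ev_val, ref_val, criteria, low_dose_cutoff)

    denom = _denominators(criteria, ref_val)
    dd2 = None if np.isscalar(denom) else denom ** 2

    kept_idx = np.nonzero(keep)[0]
    dt2 = criteria.dist_tol ** 2
    ref_tree = cKDTree(ref_pos)
    ev_tree = cKDTree(ev_pos[kept_idx])
    pairs = ev_tree.sparse_distance_matrix(ref_tree, radius, output_type="ndarray")
    dv = ref_val[pairs["j"]] - ev_val[kept_idx][pairs["i"]]
    if dd2 is None:
        g2 = pairs["v"] ** 2 / dt2 + dv ** 2 / denom ** 2
    else:
        g2 = pairs["v"] ** 2 / dt2 + dv ** 2 / dd2[pairs["j"]]
    best = np.full(kept_idx.shape, np.inf)
    np.minimum.at(best, pairs["i"], g2)
    best = np.sqrt(best)
    capped = best > cap
    best[capped] = cap
    n_capped = int(capped.sum())
    gamma = np.full(ev_val.shape, np.nan)
    gamma[kept_idx] = best

    n_eval = int(keep.sum())
    pass_fraction = float(np.sum(gamma[keep] <= 1.0)) / n_eval if n_eval else 0.0
    shape = evaluated.values.shape if isinstance(evaluated, DoseGrid) else gamma.shape
    return GammaResult(gamma_values=gamma.reshape(shape), pass_fraction=pass_fraction,
                       criteria=criteria, n_evaluated=n_eval, n_capped=n_capped,
                       cap=cap)


def gamma_map_bruteforce(reference: ScanCurve | DoseGrid,
                         evaluated: ScanCurve | DoseGrid,
                         criteria: Criteria,
                         low_dose_cutoff: float | None = None,
                         search_radius: float | None = None,
                         subsample: float | None = None) -> GammaResult:
    """Exhaustive-search gamma: scans every reference sample per point.

    Uses the same subsampling and cap as :func:`gamma_map` so the two
    routes agree exactly; serves as the independent reference
    implementation for validating the radius-limited search.
    """
    _check_overlap(reference, evaluated)
    radius = 3.0 * criteria.dist_tol if search_radius is None else search_radius
    sub = criteria.dist_tol / 3.0 if subsample is None else subsample
    cap = radius / criteria.dist_tol

    ref_pos, ref_val = _ref_samples(reference, sub)
    ev_pos, ev_val = _eval_points(evaluated)
    keep = _cutoff_mask(ev_val, ref_val, criteria, low_dose_cutoff)
    denom = _denominators(criteria, ref_val)
    dd2 = denom ** 2 if not np.isscalar(denom) else None
    dt2 = criteria.dist_tol ** 2

    gamma = np.full(ev_val.shape, np.nan)
    n_capped = 0
    for i in np.nonzero(keep)[0]:
        dr2 = np.sum((ref_pos - ev_pos[i]) ** 2, axis=-1)
        dv = ref_val - ev_val[i]
        if dd2 is None:
            g2 = dr2 / dt2 + dv ** 2 / denom ** 2
        else:
            g2 = dr2 / dt2 + dv ** 2 / dd2
        g = math.sqrt(float(np.min(g2)))
        if g > cap:
            g = cap
            n_capped += 1
        gamma[i] = g
    n_eval = int(keep.sum())
    pass_fraction = float(np.sum(gamma[keep] <= 1.0)) / n_eval if n_eval else 0.0
    shape = evaluated.values.shape if isinstance(evaluated, DoseGrid) else gamma.shape
    return GammaResult(gamma_values=gamma.reshape(shape), pass_fraction=pass_fraction,
                       criteria=criteria, n_evaluated=n_eval, n_capped=n_capped,
                       cap=cap)


def planar_comparison(reference: DoseGrid, evaluated: DoseGrid,
                      criteria: Criteria, pass_threshold: float = 90.0,
                      **gamma_kwargs) -> tuple[GammaResult, bool]:
    """Planar gamma analysis plus the clinical pass/fail decision.

    ``clinical_pass`` is true when the percentage of pixels with gamma
    ≤ 1 meets ``pass_threshold`` (default 90%).
    """
    result = gamma_map(reference, evaluated, criteria, **gamma_kwargs)
    return result, bool(100.0 * result.pass_fraction >= pass_threshold)
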