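"""Analytic water-phantom beam data with controllable discrepancies.

The generators emulate the qualitative features of megavoltage photon
beams in water that the commissioning analysis exercises, without any
claim of matching a named linac:

* PDD: build-up then quasi-exponential falloff,
  ``v(z) ∝ (1 - exp(-β z)) · exp(-μ z)`` with build-up coefficient β and
  effective attenuation μ; the analytic peak sits at
  ``z* = ln((β + μ)/μ) / β``.
* Lateral profile: difference of two error-function edges centered at
  the projected field half-width, a parabolic horn term, and a constant
  low tail; normalized to 100 on the central axis.
* Planar dose: superposition of rectangular and Gaussian fluence
  elements, optionally smoothed by a Gaussian kernel (zero padding, so
  the integral is conserved up to boundary leakage).
* Point-dose cohorts: per-patient true dose with configurable
  per-technique systematic bias and Gaussian noise on each of the TPS,
  VS and ion-chamber readings.

Every generator is a pure function of its parameters and an explicit
seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.special import erf

from beamcheck.io import (DoseGrid, PointDoseRecord, ScanCurve,
                          write_dose_grid, write_point_doses, write_scan_table)


@dataclass(frozen=True)
class BeamModelParams:
    """Analytic beam-shape parameters.

    ``dmax_depth`` (mm) is the nominal depth of maximum dose;
    ``attenuation_mu`` and ``buildup_beta`` (1/mm) shape the PDD;
    ``penumbra_sigma`` (mm) the error-function edge width;
    ``tail_fraction`` the constant out-of-field pedestal as a fraction
    of the central-axis dose; ``horn_amplitude`` the relative parabolic
    in-field horn height.
    """

    dmax_depth: float
    attenuation_mu: float
    buildup_beta: float
    penumbra_sigma: float
    tail_fraction: float = 0.0
    horn_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.dmax_depth <= 0:
            raise ValueError("dmax_depth must be > 0")
        if self.attenuation_mu <= 0:
            raise ValueError("attenuation_mu must be > 0")
        if self.buildup_beta <= self.attenuation_mu:
            raise ValueError("buildup_beta must exceed attenuation_mu")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")
        if not 0 <= self.tail_fraction < 0.2:
            raise ValueError("tail_fraction must be in [0, 0.2)")

    @property
    def analytic_peak_depth(self) -> float:
        """Exact arg-max depth (mm) of the analytic PDD form."""
        mu, beta = self.attenuation_mu, self.buildup_beta
        return math.log((beta + mu) / mu) / beta


def _preset(mu: float, beta: float, sigma: float, tail: float,
            horn: float) -> BeamModelParams:
    peak = math.log((beta + mu) / mu) / beta
    return BeamModelParams(dmax_depth=peak, attenuation_mu=mu, buildup_beta=beta,
                           penumbra_sigma=sigma, tail_fraction=tail,
                           horn_amplitude=horn)


#: Qualitative energy presets ("6x-like" etc.); peak depths ~15/28/32 mm.
PRESETS: dict[str, BeamModelParams] = {
    "6x": _preset(mu=0.0046, beta=0.27, sigma=2.2, tail=0.015, horn=0.03),
    "15x": _preset(mu=0.0036, beta=0.128, sigma=2.8, tail=0.02, horn=0.02),
    "18x": _preset(mu=0.0034, beta=0.11, sigma=3.0, tail=0.02, horn=0.015),
}


@dataclass(frozen=True)
class Perturbation:
    """Controlled discrepancy applied to a curve.

    ``lateral_shift`` (mm, profiles only), ``output_scale`` multiplier,
    ``sigma_delta`` (mm) of additional Gaussian edge blur (profiles
    only), ``noise_sd`` additive Gaussian noise as percent of the
    central-axis value, with a mandatory ``seed``.
    """

    lateral_shift: float = 0.0
    output_scale: float = 1.0
    sigma_delta: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_scale <= 0:
            raise ValueError("output_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sigma_delta < 0:
            raise ValueError("sigma_delta must be >= 0")


# ---------------------------------------------------------------------------
# curve generators
# ---------------------------------------------------------------------------


def make_pdd(params: BeamModelParams, z_max: float = 350.0, step: float = 1.0,
             energy_label: str = "6x", field_x: float = 100.0,
             field_y: float | None = None, ssd: float = 1000.0,
             collimation: str = "jaw", source: str = "synthetic") -> ScanCurve:
    """Analytic percent-depth-dose curve from the surface to ``z_max`` mm.

    ``v(z) = (1 - exp(-β z)) · exp(-μ z)`` in raw (arbitrary) units;
    downstream analysis renormalizes to Dmax = 100.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if z_max <= step:
        raise ValueError("z_max must exceed step")
    z = step * np.arange(int(math.floor(z_max / step + 1e-9)) + 1)
    v = (1.0 - np.exp(-params.buildup_beta * z)) * np.exp(-params.attenuation_mu * z)
    return ScanCurve(axis="depth", positions=z, values=v,
                     energy_label=energy_label, field_x=field_x,
                     field_y=field_x if field_y is None else field_y,
                     ssd=ssd, collimation=collimation, source=source)


def make_profile(params: BeamModelParams, field_x: float, depth: float,
                 field_y: float | None = None, axis: str = "crossline",
                 ssd: float = 1000.0, collimation: str = "jaw",
                 energy_label: str = "6x", source: str = "synthetic",
                 step: float = 1.0, extent: float | None = None) -> ScanCurve:
    """Analytic lateral profile at ``depth`` mm, normalized to CAX = 100.

    The core is the difference of two error-function edges centered at
    the projected half-width ``(field/2) · (ssd + depth)/ssd`` with width
    ``penumbra_sigma``; a parabolic horn term and a constant tail
    pedestal are added before renormalization.  The default extent
    covers the 20% positions plus comfortably more than the 15 mm tail.
    """
    if field_x <= 0:
        raise ValueError("field width must be > 0")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if axis == "depth":
        raise ValueError("profiles must be crossline or inline")
    field_y = field_x if field_y is None else field_y
    width = field_x if axis == "crossline" else field_y
    a = 0.5 * width * (ssd + depth) / ssd
    s = params.penumbra_sigma
    if extent is None:
        extent = step * math.ceil((a + 8.0 * s + 25.0) / step)
    n = int(math.floor(extent / step + 1e-9))
    x = step * np.arange(-n, n + 1)

    c = s * math.sqrt(2.0)
    core = 0.5 * (erf((x + a) / c) - erf((x - a) / c))
    core0 = float(erf(a / c))
    core_unit = core / core0
    horn = 1.0 + params.horn_amplitude * (x / a) ** 2
    raw = core_unit * horn + params.tail_fraction
    v = 100.0 * raw / (1.0 + params.tail_fraction)  # CAX (x=0) -> exactly 100
    return ScanCurve(axis=axis, positions=x, values=v, energy_label=energy_label,
                     field_x=field_x, field_y=field_y, ssd=ssd, scan_depth=depth,
                     collimation=collimation, source=source)


def perturb_curve(curve: ScanCurve, p: Perturbation,
                  source: str | None = None) -> ScanCurve:
    """Apply a controlled discrepancy: shift, scale, edge blur, then noise.

    Deterministic for a fixed ``p.seed``.  The identity perturbation
    returns the curve's data unchanged.
    """
    if curve.axis == "depth" and p.lateral_shift != 0:
        raise ValueError("lateral_shift is meaningless on a depth-axis curve")
    positions = curve.positions + (p.lateral_shift if curve.is_profile else 0.0)
    values = curve.values * p.output_scale
    if p.sigma_delta > 0 and curve.is_profile:
        values = _reblur(positions, values, p.sigma_delta)
    if p.noise_sd > 0:
        if curve.is_profile:
            cax = float(np.interp(0.0, positions, values))
        else:
            cax = float(np.max(values))
        rng = np.random.default_rng(p.seed)
        values = values + rng.normal(0.0, p.noise_sd / 100.0 * cax, size=values.shape)
        values = np.maximum(values, 0.0)
    meta = {} if source is None else {"source": source}
    return curve.with_data(positions, values, **meta)


def _reblur(positions: np.ndarray, values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-convolve a sampled curve by ``sigma`` mm."""
    steps = np.diff(positions)
    if np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        return gaussian_filter1d(values, sigma / steps[0], mode="nearest")
    # non-uniform grid: blur on a temporary uniform grid, interpolate back
    h = float(np.min(steps))
    grid = np.arange(positions[0], positions[-1] + h / 2, h)
    blurred = gaussian_filter1d(np.interp(grid, positions, values),
                                sigma / h, mode="nearest")
    return np.interp(positions, grid, blurred)


# ---------------------------------------------------------------------------
# planar dose
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluenceRect:
    """Uniform rectangle: center (mm, grid-axis order), size (mm), amplitude (Gy)."""

    center: tuple[float, float]
    size: tuple[float, float]
    amplitude: float


@dataclass(frozen=True)
class FluenceGaussian:
    """Isotropic Gaussian blob: center (mm), sigma (mm), peak amplitude (Gy)."""

    center: tuple[float, float]
    sigma: float
    amplitude: float


def make_dose_plane(elements: Sequence[FluenceRect | FluenceGaussian],
                    spacing: float, extent: float,
                    smooth_sigma: float = 0.0,
                    frame_label: str = "") -> DoseGrid:
    """Superpose fluence elements on a square plane centered at the origin.

    ``extent`` is the full side length (mm); voxel centers are spaced
    ``spacing`` mm.  With ``smooth_sigma > 0`` the summed pattern is
    convolved with a Gaussian kernel using zero padding, which conserves
    the dose integral apart from leakage past the boundary.
    """
    if not elements:
        raise ValueError("at least one fluence element is required")
    if spacing <= 0 or extent <= spacing:
        raise ValueError("need spacing > 0 and extent > spacing")
    n = int(math.floor(extent / (2 * spacing) + 1e-9))
    coords = spacing * np.arange(-n, n + 1)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    values = np.zeros_like(yy)
    for el in elements:
        if isinstance(el, FluenceRect):
            inside = (np.abs(yy - el.center[0]) <= el.size[0] / 2 + 1e-9) & \
                     (np.abs(xx - el.center[1]) <= el.size[1] / 2 + 1e-9)
            values += el.amplitude * inside
        elif isinstance(el, FluenceGaussian):
            r2 = (yy - el.center[0]) ** 2 + (xx - el.center[1]) ** 2
            values += el.amplitude * np.exp(-0.5 * r2 / el.sigma ** 2)
        else:
            raise TypeError(f"unknown fluence element {type(el).__name__}")
    if smooth_sigma > 0:
        values = gaussian_filter(values, smooth_sigma / spacing, mode="constant")
    return DoseGrid(origin=(coords[0], coords[0]), spacing=(spacing, spacing),
                    values=values, frame_label=frame_label)


# ---------------------------------------------------------------------------
# point-dose cohorts
# ---------------------------------------------------------------------------


def _per_technique(bias: float | tuple[float, float]) -> tuple[float, float]:
    """Normalize a bias argument to an (IMRT, VMAT) pair."""
    if np.isscalar(bias):
        return float(bias), float(bias)
    imrt, vmat = bias
    return float(imrt), float(vmat)


def make_point_dose_cohort(n: int,
                           bias_tps: float | tuple[float, float] = 0.0,
                           bias_vs: float | tuple[float, float] = 0.0,
                           sd_tps: float = 0.0, sd_vs: float = 0.0,
                           sd_ic: float = 0.0,
                           vmat_fraction: float = 0.3,
                           seed: int = 0,
                           dose_range: tuple[float, float] = (1.5, 3.0),
                           ) -> list[PointDoseRecord]:
    """Synthetic patient cohort of TPS/VS/ion-chamber dose triplets.

    Each patient has a true dose drawn uniformly from ``dose_range``
    (Gy); the ion chamber reads ``true·(1 + ε_ic)`` and each calculation
    ``true·(1 + bias + ε)`` with ε ~ N(0, sd).  Biases may be a scalar
    or an ``(IMRT, VMAT)`` pair to model technique-dependent systematic
    offsets.  ``round(n · vmat_fraction)`` patients are labelled VMAT.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min(sd_tps, sd_vs, sd_ic) < 0:
        raise ValueError("noise sds must be >= 0")
    if not 0 <= vmat_fraction <= 1:
        raise ValueError("vmat_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    b_tps = _per_technique(bias_tps)
    b_vs = _per_technique(bias_vs)

    n_vmat = int(round(n * vmat_fraction))
    is_vmat = np.zeros(n, dtype=bool)
    is_vmat[rng.permutation(n)[:n_vmat]] = True

    true = rng.uniform(dose_range[0], dose_range[1], size=n)
    eps_ic = rng.standard_normal(n) * sd_ic
    eps_tps = rng.standard_normal(n) * sd_tps
    eps_vs = rng.standard_normal(n) * sd_vs

    records = []
    for i in range(n):
        tech = "VMAT" if is_vmat[i] else "IMRT"
        bt = b_tps[1] if is_vmat[i] else b_tps[0]
        bv = b_vs[1] if is_vmat[i] else b_vs[0]
        records.append(PointDoseRecord(
            patient_id=f"P{i + 1:03d}", technique=tech,
            dose_tps=float(true[i] * (1.0 + bt + eps_tps[i])),
            dose_vs=float(true[i] * (1.0 + bv + eps_vs[i])),
            dose_ic=float(true[i] * (1.0 + eps_ic[i]))))
    return records


# ---------------------------------------------------------------------------
# full commissioning dataset
# ---------------------------------------------------------------------------

JAW_FIELDS_CM = (3, 4, 5, 10, 15, 20, 25, 30, 40)
MLC_FIELDS_CM = (1, 2)

#: per-source beam-model tweaks and perturbations for the non-identity dataset
_SOURCE_MODEL = {
    # (mu_scale, sigma_add_mm, tail_add, lateral_shift_mm, output_scale, noise_pct)
    "measured": (1.0, 0.0, 0.0, 0.0, 1.0, 0.15),
    "tps": (0.99, 0.2, 0.002, 0.2, 1.002, 0.1),
    "vs": (1.03, 0.5, 0.008, 0.5, 1.005, 0.1),
}


def profile_depths(energy: str, params: BeamModelParams) -> list[float]:
    """Scan depths (mm) per energy: four from Dmax to 220 mm, five (to 300 mm) for 15x."""
    dmax = round(params.analytic_peak_depth)
    depths = [float(dmax), 50.0, 100.0, 220.0]
    if energy == "15x":
        depths.append(300.0)
    return depths


def make_commissioning_dataset(out_dir: str | Path, seed: int,
                               energies: Sequence[str] = ("6x", "15x", "18x"),
                               identity: bool = False,
                               n_patients: int = 40,
                               n_planar_cases: int = 6,
                               plane_spacing: float = 2.0,
                               plane_extent: float = 120.0) -> dict:
    """Write a complete synthetic commissioning dataset to ``out_dir``.

    Produces ``scans.csv`` (PDDs and crossline profiles for every energy
    × field size × depth × source), ``planes/case*_{tps,vs,film}.txt``
    planar doses, and ``point_doses.csv``.  With ``identity=True`` every
    source is byte-identical (no discrepancies, no noise) — the dataset
    on which every comparison must report zero error and 100% pass.

    Returns a manifest dict of the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    curves: list[ScanCurve] = []
    for energy in energies:
        base = PRESETS[energy]
        depths = profile_depths(energy, base)
        fields = [(f * 10.0, "jaw") for f in JAW_FIELDS_CM] + \
                 [(f * 10.0, "mlc") for f in MLC_FIELDS_CM]
        for width, collim in fields:
            for src in ("measured", "tps", "vs"):
                params, perturb = _source_setup(base, src, identity, rng)
                pdd = make_pdd(params, z_max=350.0, step=1.0, energy_label=energy,
                               field_x=width, collimation=collim, source=src)
                curves.append(perturb_curve(pdd, replace(perturb, lateral_shift=0.0),
                                            source=src))
                for depth in depths:
                    prof = make_profile(params, field_x=width, depth=depth,
                                        energy_label=energy, collimation=collim,
                                        source=src)
                    curves.append(perturb_curve(prof, _reseed(perturb, rng),
                                                source=src))
    scans_path = write_scan_table(curves, out_dir / "scans.csv")

    planes_dir = out_dir / "planes"
    planes_dir.mkdir(exist_ok=True)
    plane_paths = []
    for case in range(1, n_planar_cases + 1):
        elements = _random_case_elements(rng)
        offsets = {"tps": (0.0, 1.0, 0.0),
                   "vs": (0.3, 1.005, 0.0),
                   "film": (0.5, 0.995, 1.0)}  # (shift mm, scale, noise % of max)
        base_plane = make_dose_plane(elements, plane_spacing, plane_extent,
                                     smooth_sigma=4.0)
        for src, (shift, scale, noise) in offsets.items():
            if identity:
                plane = base_plane
            else:
                shifted = [_shift_element(el, shift) for el in elements]
                plane = make_dose_plane(shifted, plane_spacing, plane_extent,
                                        smooth_sigma=4.0)
                values = plane.values * scale
                if noise > 0:
                    values = values + rng.normal(
                        0.0, noise / 100.0 * values.max(), size=values.shape)
                    values = np.maximum(values, 0.0)
                plane = DoseGrid(plane.origin, plane.spacing, values)
            path = planes_dir / f"case{case:02d}_{src}.txt"
            write_dose_grid(DoseGrid(plane.origin, plane.spacing, plane.values,
                                     frame_label=f"case{case:02d}/{src}"), path)
            plane_paths.append(path)

    if identity:
        cohort = make_point_dose_cohort(n_patients, seed=_child_seed(rng))
    else:
        cohort = make_point_dose_cohort(
            n_patients, bias_tps=(-0.002, 0.022), bias_vs=(-0.002, 0.015),
            sd_tps=0.015, sd_vs=0.009, sd_ic=0.005,
            vmat_fraction=0.3, seed=_child_seed(rng))
    points_path = write_point_doses(cohort, out_dir / "point_doses.csv")

    return {"scans": scans_path, "planes": plane_paths, "point_doses": points_path,
            "n_curves": len(curves)}


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _reseed(p: Perturbation, rng: np.random.Generator) -> Perturbation:
    return replace(p, seed=_child_seed(rng))


def _source_setup(base: BeamModelParams, src: str, identity: bool,
                  rng: np.random.Generator) -> tuple[BeamModelParams, Perturbation]:
    if identity:
        return base, Perturbation(seed=_child_seed(rng))
    mu_scale, sigma_add, tail_add, shift, scale, noise = _SOURCE_MODEL[src]
    params = BeamModelParams(
        dmax_depth=base.dmax_depth,
        attenuation_mu=base.attenuation_mu * mu_scale,
        buildup_beta=base.buildup_beta,
        penumbra_sigma=base.penumbra_sigma + sigma_add,
        tail_fraction=base.tail_fraction + tail_add,
        horn_amplitude=base.horn_amplitude)
    return params, Perturbation(lateral_shift=shift, output_scale=scale,
                                noise_sd=noise, seed=_child_seed(rng))


def _random_case_elements(rng: np.random.Generator) -> list:
    """IMRT-like pattern: a few overlapping rectangles plus Gaussian blobs."""
    elements: list = []
    for _ in range(int(rng.integers(2, 5))):
        cy, cx = rng.uniform(-25, 25, size=2)
        h, w = rng.uniform(25, 70, size=2)
        elements.append(FluenceRect(center=(cy, cx), size=(h, w),
                                    amplitude=float(rng.uniform(0.5, 1.5))))
    for _ in range(int(rng.integers(1, 3))):
        cy, cx = rng.uniform(-20, 20, size=2)
        elements.append(FluenceGaussian(center=(cy, cx),
                                        sigma=float(rng.uniform(8, 18)),
                                        amplitude=float(rng.uniform(0.3, 0.8))))
    return elements


def _shift_element(el, shift: float):
    center = (el.center[0] + shift, el.center[1] + shift)
    return replace(el, center=center)
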