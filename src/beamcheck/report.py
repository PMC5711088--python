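"""End-to-end commissioning run and summary-table rendering.

:func:`run_commissioning` walks a dataset directory::

    dataset_root/
      scans.csv            # PDDs and profiles, all energies/fields/sources
      planes/              # optional planar doses: case*_{tps,vs,film}.txt
      point_doses.csv      # optional patient point-dose triplets

and produces a :class:`CommissioningReport` holding the standard
commissioning summary tables:

* per energy × field size PDD error (mean ± sd, TPS and VS vs measured);
* per energy profile tables over jaw-collimated fields — in-field error,
  penumbral DTA pass rate (2%/2 mm), out-of-field (tail) error;
* the small-field table for MLC-collimated fields (width ≤ 2 cm), where
  there is no flat core and the in-field is scored as a 1.5%/1.5 mm DTA
  pass rate instead of a mean difference;
* point-dose ratio summaries (Total / VMAT / IMRT);
* planar gamma pass statistics (3%/3 mm) for the VS↔TPS, TPS↔film and
  VS↔film pairs.

The run is a pure function of (dataset, config): tables iterate in
sorted order and rendering uses fixed formatting, so repeated runs
produce byte-identical output.  Partial datasets produce partial
reports with logged omissions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from beamcheck.curves import (AnalysisConfig, field_label, infield_difference,
                              mean_pdd_error, normalize_pdd, normalize_profile,
                              pool_differences, resample, segment_profile,
                              tail_difference)
from beamcheck.errors import ConfigurationError, DataError
from beamcheck.gamma import Criteria, composite_pass_rate, planar_comparison
from beamcheck.io import ScanCurve, read_dose_grid, read_point_doses, read_scan_table
from beamcheck.points import aggregate_ratios

log = logging.getLogger(__name__)

COMPARISONS = ("tps", "vs")
PLANE_PAIRS = (("vs_tps", "tps", "vs"),
               ("tps_film", "film", "tps"),
               ("vs_film", "film", "vs"))


@dataclass
class CommissioningReport:
    """All summary tables of one commissioning run plus the config used."""

    pdd_table: pd.DataFrame
    profile_tables: dict[str, pd.DataFrame]
    smallfield_table: pd.DataFrame
    point_dose_table: pd.DataFrame | None
    gamma_table: pd.DataFrame | None
    config_echo: AnalysisConfig


def _is_smallfield(curve: ScanCurve, config: AnalysisConfig) -> bool:
    return curve.collimation == "mlc" and \
        min(curve.field_x, curve.field_y) <= config.smallfield_max_width


def _prepare_pdd(curve: ScanCurve, config: AnalysisConfig) -> ScanCurve:
    return normalize_pdd(resample(curve, config.resample_step))[0]


def _prepare_profile(curve: ScanCurve, config: AnalysisConfig) -> ScanCurve:
    return normalize_profile(resample(curve, config.resample_step))


def run_commissioning(dataset_root: str | Path,
                      config: AnalysisConfig | None = None) -> CommissioningReport:
    """Run the full commissioning analysis over a dataset directory."""
    config = config or AnalysisConfig()
    root = Path(dataset_root)
    scans_path = root / "scans.csv"
    if not scans_path.exists():
        raise ConfigurationError(f"no scan table at {scans_path}")
    curves = read_scan_table(scans_path)

    by_key: dict[tuple, dict[str, ScanCurve]] = {}
    for c in curves:
        key = (c.energy_label, c.field_x, c.field_y, c.collimation, c.axis,
               c.scan_depth)
        by_key.setdefault(key, {})[c.source] = c

    pdd_rows, profile_rows, smallfield_rows = [], [], []
    field_keys = sorted({(k[0], k[1], k[2], k[3]) for k in by_key})
    if not any("measured" in grp for grp in by_key.values()):
        raise ConfigurationError("dataset contains no measured reference curves")

    for energy, fx, fy, collim in field_keys:
        pdd_group = by_key.get((energy, fx, fy, collim, "depth", None), {})
        if pdd_group:
            pdd_rows.append(_pdd_row(energy, pdd_group, config))
        prof_keys = sorted(k for k in by_key
                           if k[:4] == (energy, fx, fy, collim) and k[4] != "depth")
        if not prof_keys:
            continue
        row = _profile_row(energy, fx, fy, collim,
                           [by_key[k] for k in prof_keys], config)
        if row is not None:
            sample = by_key[prof_keys[0]].get("measured") or \
                next(iter(by_key[prof_keys[0]].values()))
            if _is_smallfield(sample, config):
                smallfield_rows.append(row)
            else:
                profile_rows.append(row)

    pdd_table = pd.DataFrame(pdd_rows)
    profile_df = pd.DataFrame(profile_rows)
    profile_tables = {e: g.drop(columns="energy").reset_index(drop=True)
                      for e, g in profile_df.groupby("energy", sort=True)} \
        if len(profile_df) else {}
    smallfield_table = pd.DataFrame(smallfield_rows)

    point_table = None
    points_path = root / "point_doses.csv"
    if points_path.exists():
        summaries = aggregate_ratios(read_point_doses(points_path))
        point_table = pd.DataFrame([s.__dict__ for s in summaries])
    else:
        log.info("no point_doses.csv; point-dose table omitted")

    gamma_table = _gamma_table(root / "planes", config)

    return CommissioningReport(pdd_table=pdd_table, profile_tables=profile_tables,
                               smallfield_table=smallfield_table,
                               point_dose_table=point_table,
                               gamma_table=gamma_table, config_echo=config)


def _pdd_row(energy: str, group: dict[str, ScanCurve],
             config: AnalysisConfig) -> dict:
    if "measured" not in group:
        raise ConfigurationError(
            f"PDD comparison for {energy} lacks a measured reference")
    ref = _prepare_pdd(group["measured"], config)
    row: dict = {"energy": energy, "field": field_label(group["measured"])}
    for cmp in COMPARISONS:
        if cmp not in group:
            log.info("PDD %s %s: no %s curve; comparison omitted",
                     energy, row["field"], cmp)
            row.update({f"{cmp}_mean": np.nan, f"{cmp}_sd": np.nan, f"{cmp}_n": 0})
            continue
        summary = mean_pdd_error(ref, _prepare_pdd(group[cmp], config), config)
        row.update({f"{cmp}_mean": summary.mean_diff, f"{cmp}_sd": summary.sd_diff,
                    f"{cmp}_n": summary.n_points})
    return row


def _profile_row(energy: str, fx: float, fy: float, collim: str,
                 depth_groups: list[dict[str, ScanCurve]],
                 config: AnalysisConfig) -> dict | None:
    """Pool one field size's profiles over depths into one table row."""
    prepared = []
    for group in depth_groups:
        if "measured" not in group:
            raise ConfigurationError(
                f"profile comparison for {energy} {fx / 10:g}x{fy / 10:g} "
                f"lacks a measured reference")
        ref = _prepare_profile(group["measured"], config)
        try:
            regions = segment_profile(ref, config)
        except DataError as exc:
            log.info("profile %s %gx%g at depth %s: segmentation skipped (%s)",
                     energy, fx / 10, fy / 10, group["measured"].scan_depth, exc)
            continue
        prepared.append((group, ref, regions))
    if not prepared:
        return None

    sample = prepared[0][0]["measured"]
    smallfield = _is_smallfield(sample, config)
    pen_crit = Criteria(*config.penumbra_criteria, norm_mode="global_cax")
    sf_crit = Criteria(*config.smallfield_infield_criteria, norm_mode="global_cax")
    row: dict = {"energy": energy, "field": field_label(sample)}

    for cmp in COMPARISONS:
        infield_parts, tail_parts, pen_rates, sf_rates = [], [], [], []
        for group, ref, regions in prepared:
            if cmp not in group:
                continue
            test = _prepare_profile(group[cmp], config)
            if smallfield:
                sf_rates.append(composite_pass_rate(
                    ref, test, regions.infield, sf_crit))
            else:
                infield_parts.append(infield_difference(ref, test, regions))
            pen_rates.append(composite_pass_rate(
                ref, test, (regions.penumbra_left, regions.penumbra_right),
                pen_crit))
            try:
                tail_parts.append(tail_difference(ref, test, regions))
            except DataError as exc:
                log.info("tail analysis skipped for %s %s (%s): %s",
                         energy, row["field"], cmp, exc)
        if not pen_rates:
            log.info("profiles %s %s: no %s curves; comparison omitted",
                     energy, row["field"], cmp)
            for col in ("infield_mean", "infield_sd", "infield_dta",
                        "infield_dta_sd", "penumbra_dta", "penumbra_dta_sd",
                        "tail_mean", "tail_sd"):
                row[f"{cmp}_{col}"] = np.nan
            row[f"{cmp}_n_depths"] = 0
            continue
        if smallfield:
            row[f"{cmp}_infield_dta"] = 100.0 * float(np.mean(sf_rates))
            row[f"{cmp}_infield_dta_sd"] = _pct_sd(sf_rates)
        else:
            pooled = pool_differences(infield_parts, row["field"])
            row[f"{cmp}_infield_mean"] = pooled.mean_diff
            row[f"{cmp}_infield_sd"] = pooled.sd_diff
        row[f"{cmp}_penumbra_dta"] = 100.0 * float(np.mean(pen_rates))
        row[f"{cmp}_penumbra_dta_sd"] = _pct_sd(pen_rates)
        if tail_parts:
            tails = pool_differences(tail_parts, row["field"])
            row[f"{cmp}_tail_mean"] = tails.mean_diff
            row[f"{cmp}_tail_sd"] = tails.sd_diff
        else:
            row[f"{cmp}_tail_mean"] = np.nan
            row[f"{cmp}_tail_sd"] = np.nan
        row[f"{cmp}_n_depths"] = len(pen_rates)
    return row


def _pct_sd(rates: list[float]) -> float:
    return 100.0 * float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0


def _gamma_table(planes_dir: Path, config: AnalysisConfig) -> pd.DataFrame | None:
    if not planes_dir.is_dir():
        log.info("no planes/ directory; planar gamma table omitted")
        return None
    pattern = re.compile(r"^(?P<case>.+)_(?P<source>tps|vs|film)\.txt$")
    cases: dict[str, dict[str, Path]] = {}
    for path in sorted(planes_dir.iterdir()):
        m = pattern.match(path.name)
        if m:
            cases.setdefault(m.group("case"), {})[m.group("source")] = path
    if not cases:
        return None
    criteria = Criteria(*config.planar_gamma_criteria, norm_mode="global_max")
    rows = []
    for pair_label, ref_src, ev_src in PLANE_PAIRS:
        passes, clinical = [], []
        for case in sorted(cases):
            files = cases[case]
            if ref_src not in files or ev_src not in files:
                log.info("case %s: missing %s or %s plane; %s omitted",
                         case, ref_src, ev_src, pair_label)
                continue
            result, ok = planar_comparison(
                read_dose_grid(files[ref_src]), read_dose_grid(files[ev_src]),
                criteria, pass_threshold=config.planar_pass_threshold)
            passes.append(100.0 * result.pass_fraction)
            clinical.append(ok)
        if passes:
            rows.append({
                "comparison": pair_label, "n_cases": len(passes),
                "mean_pass_pct": float(np.mean(passes)),
                "sd_pass_pct": float(np.std(passes, ddof=1)) if len(passes) > 1 else 0.0,
                "n_clinical_pass": int(sum(clinical)),
            })
    return pd.DataFrame(rows) if rows else None


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_report(report: CommissioningReport, out_dir: str | Path,
                  format: str = "csv") -> list[Path]:
    """Write one file per summary table (CSV or markdown) plus the config echo.

    CSV keeps mean and sd in separate full-precision columns so cells
    re-parse to the report's numbers exactly; markdown renders
    ``mean±sd`` cells rounded to two decimals.
    """
    if format not in ("csv", "markdown"):
        raise ValueError("format must be 'csv' or 'markdown'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if format == "csv" else "md"
    written: list[Path] = []

    tables: list[tuple[str, pd.DataFrame | None]] = [
        ("pdd_summary", report.pdd_table)]
    for energy in sorted(report.profile_tables):
        tables.append((f"profiles_{energy}", report.profile_tables[energy]))
    tables += [("smallfield", report.smallfield_table),
               ("point_doses", report.point_dose_table),
               ("gamma", report.gamma_table)]

    for name, table in tables:
        if table is None or len(table) == 0:
            continue
        path = out_dir / f"{name}.{ext}"
        if format == "csv":
            path.write_text(table.to_csv(index=False), encoding="utf-8")
        else:
            path.write_text(_to_markdown(table), encoding="utf-8")
        written.append(path)

    cfg_path = report.config_echo.to_yaml(out_dir / "config.yaml")
    written.append(cfg_path)
    return written


def _to_markdown(table: pd.DataFrame) -> str:
    """Markdown with mean/sd column pairs merged into ``mean±sd`` cells."""
    merged = table.copy()
    for col in list(merged.columns):
        if col.endswith("_mean") and col[:-5] + "_sd" in merged.columns:
            base = col[:-5]
            merged[base] = [
                "" if pd.isna(m) else f"{m:.2f}±{s:.2f}"
                for m, s in zip(merged[col], merged[base + "_sd"])]
            merged = merged.drop(columns=[col, base + "_sd"])
        elif col.endswith(("_dta", "_pass_pct")) and col + "_sd" in merged.columns:
            merged[col] = [
                "" if pd.isna(m) else f"{m:.2f}±{s:.2f}"
                for m, s in zip(merged[col], merged[col + "_sd"])]
            merged = merged.drop(columns=col + "_sd")
    cols = list(merged.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in merged.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                cells.append("" if pd.isna(v) else f"{v:.2f}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
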