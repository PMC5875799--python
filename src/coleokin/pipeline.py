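"""End-to-end per-plant and cohort analysis.

Chains the stages: midlines -> orientation/curvature kymographs; marker
profiles -> REGR kymograph; REGR + curvature -> material curvature
derivative; oscillation characterization of the REGR and curvature-rate
kymographs; morphometric overshoot classification (tilted plants); and
the elongation/curvature-rate coupling correlation.  Cohort mode runs
every plant in a dataset directory, tolerating per-plant failures, and
finishes with the straight-vs-tilted statistical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, morphometrics, oscillations, stats
from .config import RunConfig
from .fields import KinematicField
from .geometry import MarkerProfileSeries, MidlineSeries

log = logging.getLogger(__name__)

__all__ = ["PlantResult", "analyze_plant", "run_pipeline", "plot_kymograph"]


@dataclass
class PlantResult:
    orientation: KinematicField
    curvature: KinematicField
    regr: KinematicField | None
    curvature_rate: KinematicField | None
    osc_regr: oscillations.OscillationSummary | None
    osc_curvrate: oscillations.OscillationSummary | None
    morpho: morphometrics.MorphometricResult | None
    r_coupling: float | None
    summary: dict


def extract_fields(
    midlines: MidlineSeries,
    markers: MarkerProfileSeries | None,
    config: RunConfig | None = None,
) -> dict:
    """Kinematic kymographs from one plant's observables.

    Curvature is smoothed with the configured local-quadratic window in s
    and a short moving average over frames before the material derivative
    is formed (raw finite differences on tracked midlines are noise
    dominated).
    """
    cfg = config or RunConfig()
    orientation = geometry.orientation_profile(midlines, s_step=cfg.s_step,
                                               presmooth_mm=cfg.smooth_window_mm)
    curvature = geometry.curvature_profile(orientation, smooth=True,
                                           window_mm=cfg.smooth_window_mm)
    if cfg.smooth_frames > 1:
        curvature = _smooth_time(curvature, cfg.smooth_frames)
    out = {"orientation": orientation, "curvature": curvature,
           "regr": None, "curvature_rate": None}
    if markers is not None:
        regr = geometry.regr_from_markers(
            markers, window=cfg.dic_window, search=cfg.dic_search,
            overlap=cfg.dic_overlap, s_step=cfg.s_step,
            smooth_window_mm=cfg.regr_smooth_mm, baseline=cfg.dic_baseline)
        regr = _align_grids(regr, orientation)
        out["regr"] = regr
        # the material derivative amplifies curvature noise through two
        # further derivatives; it gets its own, more heavily smoothed
        # curvature source
        c_rate_src = geometry.curvature_profile(orientation, smooth=True,
                                                window_mm=cfg.rate_smooth_mm)
        if cfg.rate_smooth_frames > 1:
            c_rate_src = _savgol_time(c_rate_src, cfg.rate_smooth_frames)
        out["curvature_rate"] = geometry.material_curvature_derivative(
            c_rate_src, regr)
    return out


def _savgol_time(field: KinematicField, window_frames: int) -> KinematicField:
    """Local-quadratic smoothing along time per supported column run."""
    from scipy.signal import savgol_filter

    vals = field.masked_values()
    out = np.full_like(vals, np.nan)
    w = window_frames | 1
    dt = field.t_grid[1] - field.t_grid[0] if field.t_grid.size > 1 else 1.0
    for j in range(vals.shape[1]):
        col = vals[:, j]
        idx = np.flatnonzero(np.isfinite(col))
        if idx.size == 0:
            continue
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if run.size < 3:
                out[run, j] = col[run]
                continue
            wi = min(w, run.size if run.size % 2 == 1 else run.size - 1)
            if wi <= 2:
                out[run, j] = col[run]
            else:
                out[run, j] = savgol_filter(col[run], wi, 2, delta=dt)
    mask = np.isfinite(out) & field.mask
    out[~mask] = np.nan
    return field.copy_like(out, mask=mask)


def _smooth_time(field: KinematicField, n_frames: int) -> KinematicField:
    """Centered moving average over frames, respecting the support mask."""
    vals = field.masked_values()
    k = n_frames // 2
    acc = np.zeros_like(vals)
    cnt = np.zeros_like(vals)
    nt = vals.shape[0]
    for off in range(-k, k + 1):
        lo, hi = max(0, -off), min(nt, nt - off)
        seg = vals[lo + off : hi + off]
        good = np.isfinite(seg)
        acc[lo:hi][good] += seg[good]
        cnt[lo:hi][good] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
    mask = field.mask & (cnt > 0)
    sm[~mask] = np.nan
    return field.copy_like(sm, mask=mask)


def _align_grids(field: KinematicField, ref: KinematicField) -> KinematicField:
    """Pad/crop a field onto the reference (s, t) grid (same spacing)."""
    if field.same_grid(ref):
        return field
    vals = np.full((ref.t_grid.size, ref.s_grid.size), np.nan)
    mask = np.zeros_like(vals, dtype=bool)
    # match by nearest grid values (grids share spacing and origin)
    si = np.searchsorted(ref.s_grid, field.s_grid - 1e-9)
    ti = np.searchsorted(ref.t_grid, field.t_grid - 1e-9)
    ok_s = (si < ref.s_grid.size) & (np.abs(ref.s_grid[np.minimum(si, ref.s_grid.size - 1)] - field.s_grid) < 1e-6)
    ok_t = (ti < ref.t_grid.size) & (np.abs(ref.t_grid[np.minimum(ti, ref.t_grid.size - 1)] - field.t_grid) < 1e-6)
    for i_src, i_dst in zip(np.flatnonzero(ok_t), ti[ok_t]):
        vals[i_dst, si[ok_s]] = field.values[i_src, ok_s]
        mask[i_dst, si[ok_s]] = field.mask[i_src, ok_s]
    vals[~mask] = np.nan
    return KinematicField(ref.s_grid, ref.t_grid, vals, mask, field.quantity)


def analyze_plant(
    midlines: MidlineSeries,
    markers: MarkerProfileSeries | None = None,
    config: RunConfig | None = None,
    tilted: bool = True,
    characterize: bool = True,
) -> PlantResult:
    """Full kinematic analysis of a single plant."""
    cfg = config or RunConfig()
    f = extract_fields(midlines, markers, cfg)
    regr, cr = f["regr"], f["curvature_rate"]

    osc_regr = osc_cr = None
    if characterize and regr is not None:
        osc_regr = _try(lambda: oscillations.characterize_field(
            regr, cfg.peak_quantile, cfg.link_max_gap, cfg.link_max_jump,
            cfg.min_track_points), "REGR oscillations")
        osc_cr = _try(lambda: oscillations.characterize_field(
            cr, cfg.peak_quantile, cfg.link_max_gap, cfg.link_max_jump,
            cfg.min_track_points), "curvature-rate oscillations")

    morpho = None
    if regr is not None:
        morpho = _try(lambda: morphometrics.classify_plant(
            f["orientation"], f["curvature"], regr, cr, tilted=tilted,
            b_threshold=cfg.b_threshold, overshoot_delta=cfg.overshoot_delta),
            "morphometrics")

    r_coupling = None
    if regr is not None:
        def _zone_r():
            # the coupling statistic lives in the growth zone; outside it
            # both fields are near zero and only dilute r
            L_eff = morphometrics.effective_length(regr)
            zone = np.zeros_like(regr.mask)
            zone[:, regr.s_grid <= L_eff] = True
            return stats.kymograph_correlation(regr, cr, restrict_mask=zone).r
        r_coupling = _try(_zone_r, "coupling r")

    summary = {"tilted": bool(tilted)}
    if regr is not None:
        summary.update({f"mean_regr{k}": v for k, v in _avg(regr, cfg.t_split).items()})
        summary.update({f"mean_curvrate{k}": v for k, v in _avg(cr, cfg.t_split).items()})
    for name, osc in (("regr", osc_regr), ("curvrate", osc_cr)):
        if osc is not None:
            summary[f"Tp_{name}"] = osc.Tp
            summary[f"vp_{name}"] = osc.vp_median
    if morpho is not None:
        summary.update(morpho.as_dict())
    if r_coupling is not None:
        summary["r_coupling"] = r_coupling
    return PlantResult(f["orientation"], f["curvature"], regr, cr,
                       osc_regr, osc_cr, morpho, r_coupling, summary)


def _avg(field, t_split):
    d = geometry.temporal_field_average(field, t_split)
    return {"": d["overall"], "_pre": d.get("pre"), "_post": d.get("post")}


def _try(fn, what):
    try:
        return fn()
    except Exception as exc:  # per-plant stage failures are not fatal
        log.warning("%s failed: %s", what, exc)
        return None


def run_pipeline(dataset_dir: str | Path, config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Analyze every plant of a cohort dataset directory.

    Expects the generator layout (``manifest.csv`` plus per-plant
    ``midline.csv``/``markers.csv``).  Writes per-plant kymographs and
    summaries plus the cohort comparison report under ``out_dir``
    (default ``<dataset>/results``); failed plants are recorded and
    skipped.  Returns the per-plant summary table.
    """
    cfg = config or RunConfig()
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir) if out_dir else dataset_dir / "results"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(dataset_dir / "manifest.csv")
    rows, failures = [], []
    produced = []
    for _, rec in manifest.iterrows():
        plant, group = rec["plant"], rec["group"]
        t0 = time.perf_counter()
        try:
            midlines = MidlineSeries.from_csv(dataset_dir / plant / "midline.csv")
            markers_path = dataset_dir / plant / "markers.csv"
            markers = (MarkerProfileSeries.from_csv(markers_path, midlines.times)
                       if markers_path.exists() else None)
            res = analyze_plant(midlines, markers, cfg, tilted=(group == "tilted"))
        except Exception as exc:
            log.error("plant %s failed: %s", plant, exc)
            failures.append({"plant": plant, "error": str(exc)})
            continue
        pdir = out_dir / plant
        pdir.mkdir(exist_ok=True)
        for name in ("orientation", "curvature", "regr", "curvature_rate"):
            fld = getattr(res, name if name != "curvature_rate" else "curvature_rate")
            if fld is not None:
                fld.write(pdir / f"{name}.csv")
                produced.append(str(pdir / f"{name}.csv"))
        (pdir / "summary.json").write_text(json.dumps(res.summary, indent=1,
                                                      default=_jsonable))
        produced.append(str(pdir / "summary.json"))
        row = {"plant": plant, "group": group, **res.summary}
        rows.append(row)
        log.info("plant %s done in %.2f s", plant, time.perf_counter() - t0)
    per_plant = pd.DataFrame(rows)
    per_plant.to_csv(out_dir / "per_plant.csv", index=False)
    if not per_plant.empty and per_plant["group"].nunique() == 2:
        try:
            report = stats.cohort_compare(per_plant)
            report.to_csv(out_dir / "comparisons.csv", index=False)
            produced.append(str(out_dir / "comparisons.csv"))
        except ValueError as exc:
            log.warning("cohort comparison skipped: %s", exc)
    meta = {"config": cfg.as_dict(), "failures": failures, "files": produced}
    (out_dir / "run_manifest.json").write_text(json.dumps(meta, indent=1))
    return per_plant


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def plot_kymograph(field: KinematicField, out_image: str | Path,
                   cmap: str = "viridis") -> Path:
    """Render a kymograph as a raster image with labeled (s, t) axes.

    Masked cells (beyond the organ's current length) are blanked.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not field.mask.any():
        raise ValueError("cannot plot an empty field")
    fig, ax = plt.subplots(figsize=(6, 4))
    vals = np.ma.masked_invalid(field.masked_values())
    mesh = ax.pcolormesh(field.s_grid, field.t_grid, vals, cmap=cmap,
                         shading="nearest")
    ax.set_xlabel("arc length s from apex [mm]")
    ax.set_ylabel("time [h]")
    ax.set_title(f"{field.quantity} [{field.units}]")
    fig.colorbar(mesh, ax=ax)
    out_image = Path(out_image)
    fig.savefig(out_image, dpi=120)
    plt.close(fig)
    return out_image
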