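"""Midline geometry and kinematic field extraction.

Turns time series of organ midlines (ordered planar point chains, apex
first) and optional marker-intensity profiles into the four kinematic
kymographs of a growing, curving organ:

* orientation ``A(s, t)`` — zenith angle in radians, 0 = vertical up,
  clockwise positive (an organ tilted to the reader's right is at +pi/2);
* curvature ``C(s, t) = dA/ds`` in mm^-1;
* relative elongation growth rate (REGR) ``E(s, t)`` in h^-1, estimated
  from marker profiles by one-dimensional digital image correlation;
* material curvature derivative ``DC/Dt`` in mm^-1 h^-1, the rate of
  curvature change following a tissue element,
  ``DC/Dt = dC/dt + (dC/ds) * integral_0^s E(s', t) ds'``
  with the advection integral taken from the apex.

Arc length is measured from the apex (``s = 0``) everywhere, including
the advection integral's lower bound.  Many kymograph tools use a base
origin; this package does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import savgol_filter

from .fields import KinematicField

log = logging.getLogger(__name__)

__all__ = [
    "MidlineFrame",
    "MidlineSeries",
    "MarkerProfileSeries",
    "MalformedInputError",
    "resample_midline",
    "orientation_profile",
    "curvature_profile",
    "regr_from_markers",
    "material_curvature_derivative",
    "temporal_field_average",
]


class MalformedInputError(ValueError):
    """Raised for midlines or profiles that violate the input contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MidlineFrame:
    time: float  # hours
    points: np.ndarray  # (n, 2) mm, apex first

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise MalformedInputError("frame points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise MalformedInputError("midline frame needs at least 2 points")

    def arc_length(self) -> np.ndarray:
        """Cumulative arc length from the apex, per point."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length()[-1])


@dataclass
class MidlineSeries:
    """Per-frame ordered planar midlines, apex-first parameterization."""

    frames: list[MidlineFrame]
    frame_interval: float = 0.25  # hours

    def __post_init__(self) -> None:
        if not self.frames:
            raise MalformedInputError("midline series has no frames")
        times = [f.time for f in self.frames]
        if any(np.diff(times) <= 0):
            raise MalformedInputError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.frames])

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for k, f in enumerate(self.frames):
            for x, y in f.points:
                rows.append((k, f.time, x, y))
        pd.DataFrame(rows, columns=["frame_index", "time_h", "x_mm", "y_mm"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval: float | None = None) -> "MidlineSeries":
        df = pd.read_csv(path)
        required = {"frame_index", "time_h", "x_mm", "y_mm"}
        if not required.issubset(df.columns):
            raise MalformedInputError(
                f"midline file must have columns {sorted(required)}"
            )
        frames = []
        for _, grp in df.groupby("frame_index", sort=True):
            frames.append(MidlineFrame(float(grp["time_h"].iloc[0]),
                                       grp[["x_mm", "y_mm"]].to_numpy()))
        if frame_interval is None:
            t = [f.time for f in frames]
            frame_interval = float(np.median(np.diff(t))) if len(t) > 1 else 0.25
        return cls(frames, frame_interval)


@dataclass
class MarkerProfileSeries:
    """Per-frame marker intensity sampled along the midline arc length.

    Shares the apex arc-length origin with :class:`MidlineSeries`.
    """

    times: np.ndarray  # hours, per frame
    profiles: list[tuple[np.ndarray, np.ndarray]]  # (s_mm, intensity) per frame
    sampling_step: float  # mm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.profiles) != self.times.size:
            raise MalformedInputError("one profile per frame required")
        for s, inten in self.profiles:
            if np.any(np.asarray(inten) < 0):
                raise MalformedInputError("marker intensities must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for k, (s, inten) in enumerate(self.profiles):
            for si, vi in zip(s, inten):
                rows.append((k, si, vi))
        pd.DataFrame(rows, columns=["frame_index", "s_mm", "intensity"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, times: np.ndarray | None = None,
                 frame_interval: float = 0.25) -> "MarkerProfileSeries":
        df = pd.read_csv(path)
        profiles = []
        for _, grp in df.groupby("frame_index", sort=True):
            profiles.append((grp["s_mm"].to_numpy(), grp["intensity"].to_numpy()))
        if times is None:
            times = frame_interval * np.arange(len(profiles))
        step = float(np.median(np.diff(profiles[0][0])))
        return cls(np.asarray(times), profiles, step)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def resample_midline(series: MidlineSeries, target_step: float) -> MidlineSeries:
    """Re-parameterize every frame to uniform arc-length spacing, apex first.

    The new sample positions are ``0, h, 2h, ..., L`` where the final step
    may be shorter so the total length is preserved to within one step.
    """
    if target_step <= 0:
        raise ValueError("target_step must be positive")
    frames = []
    for f in series.frames:
        s = f.arc_length()
        if np.any(np.diff(s) == 0):
            raise MalformedInputError("duplicate consecutive points in frame")
        L = s[-1]
        n = int(np.floor(L / target_step + 1e-9)) + 1
        s_new = np.minimum(target_step * np.arange(n), L)
        x = np.interp(s_new, s, f.points[:, 0])
        y = np.interp(s_new, s, f.points[:, 1])
        frames.append(MidlineFrame(f.time, np.column_stack([x, y])))
    return MidlineSeries(frames, series.frame_interval)


def _frame_orientation(frame: MidlineFrame, s: np.ndarray) -> np.ndarray:
    """Zenith angle per point: 0 = vertical up, clockwise (toward +x) positive.

    Points are apex-first, so the apexward tangent is minus the derivative
    of position with respect to s.
    """
    if np.any(np.diff(s) == 0):
        raise MalformedInputError("duplicate consecutive points in frame")
    dx = np.gradient(frame.points[:, 0], s, edge_order=2)
    dy = np.gradient(frame.points[:, 1], s, edge_order=2)
    ang = np.arctan2(-dx, -dy)  # apexward tangent = -(dx, dy)
    return np.unwrap(ang)


def _common_grids(series: MidlineSeries, s_step: float) -> tuple[np.ndarray, np.ndarray]:
    L_max = series.lengths.max()
    s_grid = s_step * np.arange(int(np.floor(L_max / s_step + 1e-9)) + 1)
    return s_grid, series.times


def orientation_profile(series: MidlineSeries, s_step: float = 0.1,
                        presmooth_mm: float = 0.0) -> KinematicField:
    """Orientation kymograph A(s, t) in radians from a midline series.

    Midlines are resampled internally to ``s_step``.  Angles are unwrapped
    along s so the field has no +/-pi jumps; a vertical upward tangent
    maps to 0 and a rightward horizontal tangent to +pi/2.

    ``presmooth_mm`` > 0 smooths the resampled coordinates with a local
    quadratic of that window before tangents are taken.  Tracked midlines
    carry coordinate noise that both roughens tangents and spuriously
    inflates arc length; smoothing the point chain is how kymograph
    pipelines counter this.
    """
    rs = resample_midline(series, s_step)
    if presmooth_mm > 0:
        sm_frames = []
        for f in rs.frames:
            w = max(5, int(round(presmooth_mm / s_step)) | 1)
            n = f.points.shape[0]
            w = min(w, n if n % 2 == 1 else n - 1)
            if w > 2:
                pts = savgol_filter(f.points, w, 2, axis=0)
            else:
                pts = f.points
            sm_frames.append(MidlineFrame(f.time, pts))
        rs = resample_midline(MidlineSeries(sm_frames, rs.frame_interval), s_step)
    s_grid, t_grid = _common_grids(rs, s_step)
    nt, ns = t_grid.size, s_grid.size
    values = np.full((nt, ns), np.nan)
    mask = np.zeros((nt, ns), dtype=bool)
    for i, f in enumerate(rs.frames):
        s = f.arc_length()
        ang = _frame_orientation(f, s)
        m = s_grid <= s[-1] + 1e-9
        values[i, m] = np.interp(s_grid[m], s, ang)
        mask[i, m] = True
    return KinematicField(s_grid, t_grid, values, mask, "orientation")


def _smooth_rows(values: np.ndarray, mask: np.ndarray, window: int, order: int = 2,
                 deriv: int = 0, delta: float = 1.0) -> np.ndarray:
    """Savitzky-Golay along axis 1 applied per contiguous supported run."""
    out = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        idx = np.flatnonzero(mask[i])
        if idx.size == 0:
            continue
        # support is contiguous in practice; handle runs defensively
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            seg = values[i, run]
            w = min(window, len(run) if len(run) % 2 == 1 else len(run) - 1)
            if w <= order:
                if deriv == 0:
                    out[i, run] = seg
                elif len(run) >= 2:
                    out[i, run] = np.gradient(seg, delta)
                continue
            out[i, run] = savgol_filter(seg, w, order, deriv=deriv, delta=delta)
    return out


def curvature_profile(orientation: KinematicField, smooth: bool = False,
                      window_mm: float = 1.5) -> KinematicField:
    """Curvature C = dA/ds by centered finite differences.

    One-sided differences are used at the support edges.  With
    ``smooth=True`` a local quadratic (Savitzky-Golay) derivative with the
    given window replaces raw differencing.
    """
    if orientation.quantity != "orientation":
        raise ValueError("expected an orientation field")
    ds = orientation.ds
    vals = orientation.masked_values()
    nt, ns = vals.shape
    out = np.full_like(vals, np.nan)
    for i in range(nt):
        idx = np.flatnonzero(orientation.mask[i])
        if idx.size == 0:
            continue
        if idx.size < 3:
            raise MalformedInputError("need at least 3 supported s-samples")
        seg = vals[i, idx]
        out[i, idx] = np.gradient(seg, ds, edge_order=2)
    if smooth:
        window = max(3, int(round(window_mm / ds)) | 1)
        out = _smooth_rows(out, orientation.mask, window, deriv=0)
    mask = np.isfinite(out) & orientation.mask
    return KinematicField(orientation.s_grid, orientation.t_grid, out, mask, "curvature")


# ---------------------------------------------------------------------------
# REGR by 1-D digital image correlation
# ---------------------------------------------------------------------------

def _subpixel_peak(corr: np.ndarray) -> float:
    """Index of the correlation maximum with 3-point parabolic refinement."""
    k = int(np.argmax(corr))
    if 0 < k < corr.size - 1:
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        if np.isfinite(denom) and denom < 0:
            k = k + 0.5 * (y0 - y2) / denom
    return float(k)


def regr_from_markers(
    profiles: MarkerProfileSeries,
    window: float = 2.0,
    search: float = 1.0,
    overlap: float = 0.75,
    s_step: float = 0.1,
    smooth_window_mm: float = 3.0,
    baseline: int = 2,
) -> KinematicField:
    """REGR kymograph from marker-intensity profiles by 1-D DIC.

    For each consecutive frame pair, windows of the earlier profile are
    matched against the later profile by maximizing the normalized
    cross-correlation over integer sample lags within ``+-search`` mm,
    refined to subpixel precision with a 3-point parabola.  The
    displacement field u(s) gives the velocity v = u / dt and the REGR
    field E = dv/ds (local quadratic derivative over
    ``smooth_window_mm``).  E is reported at the earlier frame's time on
    that frame's material grid.

    ``baseline`` is the frame separation of each correlated pair (pairs
    still advance one frame at a time): separating the frames grows the
    displacement signal relative to the fixed subpixel matching error,
    at negligible temporal-resolution cost for pulse periods of hours.

    Windows with zero intensity variance, or whose displacement estimate
    hits the search bound, are masked and a warning is logged.
    """
    if len(profiles.profiles) < 2:
        raise MalformedInputError("need at least 2 frames for REGR")
    baseline = max(1, min(int(baseline), len(profiles.profiles) - 1))
    step = profiles.sampling_step
    if window <= step:
        raise ValueError("window must exceed the profile sampling step")
    half = int(round(window / 2 / step))
    max_lag = int(round(search / step))
    hop = max(1, int(round(window * (1 - overlap) / step)))

    times = profiles.times
    L_max = max(s[-1] for s, _ in profiles.profiles)
    s_grid = s_step * np.arange(int(np.floor(L_max / s_step + 1e-9)) + 1)
    nt = times.size
    values = np.full((nt, s_grid.size), np.nan)
    mask = np.zeros((nt, s_grid.size), dtype=bool)

    from numpy.lib.stride_tricks import sliding_window_view

    wlen_dic = 2 * half + 1
    nlags = 2 * max_lag + 1
    n_flat = n_bound = 0
    for i in range(nt - baseline):
        s0, I0 = profiles.profiles[i]
        s1, I1 = profiles.profiles[i + baseline]
        dt = times[i + baseline] - times[i]
        n0, n1 = I0.size, I1.size
        if n1 < wlen_dic:
            continue
        centers = np.arange(half + max_lag,
                            min(n0, n1) - half - max_lag, hop)
        if centers.size < 3:
            continue
        # all candidate windows of the later profile, normalized lazily
        win1 = sliding_window_view(I1, wlen_dic)
        sd1 = win1.std(axis=1)
        u = np.full(centers.size, np.nan)
        for j, c in enumerate(centers):
            w0 = I0[c - half : c + half + 1]
            if w0.std() == 0:
                n_flat += 1
                continue
            w0n = w0 - w0.mean()  # zero-mean, so window means of I1 drop out
            start = c - half - max_lag
            block_sd = sd1[start : start + nlags]
            corr = win1[start : start + nlags] @ w0n
            ok = block_sd > 0
            if not ok.any():
                n_flat += 1
                continue
            corr = np.where(ok, corr / np.where(ok, block_sd, 1.0), -np.inf)
            k = _subpixel_peak(corr)
            if k <= 0.5 or k >= nlags - 1.5:
                n_bound += 1
                continue
            u[j] = (k - max_lag) * step
        s_c = s0[centers]
        good = np.isfinite(u)
        if good.sum() < 5:
            continue
        v = u[good] / dt
        s_v = s_c[good]
        # anchor the velocity at the apex: material drift vanishes at s=0
        # by construction, which removes the one-sided boundary bias of
        # the derivative near the apical support edge
        hop_mm = float(np.median(np.diff(s_v)))
        s_u = np.arange(0.0, s_v[-1] + hop_mm / 2, hop_mm)
        v_u = np.interp(s_u, np.concatenate([[0.0], s_v]),
                        np.concatenate([[0.0], v]))
        # local quadratic derivative of v(s) -> REGR
        wlen = max(5, int(round(smooth_window_mm / hop_mm)) | 1)
        wlen = min(wlen, s_u.size if s_u.size % 2 == 1 else s_u.size - 1)
        if wlen > 2:
            regr = savgol_filter(v_u, wlen, 2, deriv=1, delta=hop_mm)
        else:
            regr = np.gradient(v_u, s_u)
        # basal boundary derivative is one-sided and unreliable
        s_u, regr = s_u[:-1], regr[:-1]
        m = (s_grid >= s_u[0]) & (s_grid <= s_u[-1])
        row = i + baseline // 2  # center of the displacement interval
        values[row, m] = np.interp(s_grid[m], s_u, regr)
        mask[row, m] = True
    # frames before the first / after the last displacement-interval
    # center have no estimate of their own; repeat the nearest one so the
    # kymograph spans all frames
    filled = np.flatnonzero(mask.any(axis=1))
    if filled.size:
        for i in range(filled[0]):
            values[i], mask[i] = values[filled[0]], mask[filled[0]]
        for i in range(filled[-1] + 1, nt):
            values[i], mask[i] = values[filled[-1]], mask[filled[-1]]
    if n_flat:
        log.warning("REGR: %d flat (zero-variance) windows masked", n_flat)
    if n_bound:
        log.warning("REGR: %d windows hit the +-%g mm search bound", n_bound, search)
    return KinematicField(s_grid, times, values, mask, "regr")


# ---------------------------------------------------------------------------
# material derivative
# ---------------------------------------------------------------------------

def advection_velocity(regr: KinematicField) -> np.ndarray:
    """Material drift speed v(s, t) = integral of REGR from the apex (s=0).

    Unsupported REGR cells are treated as zero growth for the cumulative
    integral, which is correct below the growth zone and conservative
    above the organ's extent.
    """
    e = np.where(regr.mask, regr.values, 0.0)
    e = np.nan_to_num(e)
    v = cumulative_trapezoid(e, regr.s_grid, axis=1, initial=0.0)
    return v


def material_curvature_derivative(
    curvature: KinematicField, regr: KinematicField
) -> KinematicField:
    """Material derivative of curvature, DC/Dt = dC/dt + v dC/ds.

    The advection velocity is the cumulative REGR integral from the apex.
    Positive values mean the curvature of the co-moving tissue element is
    increasing.  Partial derivatives are centered differences; cells whose
    finite-difference stencil leaves the joint support are masked.
    """
    if not curvature.same_grid(regr):
        raise ValueError("curvature and REGR fields must share grids")
    joint = curvature.mask & regr.mask
    C = curvature.values.copy()
    C[~joint] = np.nan
    dCdt = np.gradient(C, curvature.t_grid, axis=0)
    dCds = np.gradient(C, curvature.s_grid, axis=1)
    v = advection_velocity(regr)
    out = dCdt + dCds * v
    mask = np.isfinite(out) & joint
    out[~mask] = np.nan
    return KinematicField(curvature.s_grid, curvature.t_grid, out, mask, "curvature_rate")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def temporal_field_average(field: KinematicField, t_split: float | None = None) -> dict:
    """Mean absolute value over supported cells, optionally split in time.

    Returns ``{"overall": m}`` or, with ``t_split`` (hours),
    ``{"overall": m, "pre": m1, "post": m2}`` where "pre" covers
    ``t <= t_split``.
    """
    if not field.mask.any():
        raise ValueError("field has empty support")
    absvals = np.abs(field.values)
    out = {"overall": float(absvals[field.mask].mean())}
    if t_split is not None:
        pre = field.t_grid <= t_split
        for name, sel in (("pre", pre), ("post", ~pre)):
            m = field.mask[sel]
            out[name] = float(absvals[sel][m].mean()) if m.any() else np.nan
    return out
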