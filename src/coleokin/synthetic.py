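"""Ground-truthed synthetic coleoptile datasets.

Emulates the observable structure of a darkroom tilting experiment on
young grass coleoptiles: 15-minute frame cadence over 24 h, initial organ
length 10-20 mm with an apical growth zone, tilt treatments of 0 and
pi/2 rad, and apex-to-base propagating pulses in both the elongation rate
and the differential growth that drives curvature change.

The organ itself follows the graviception-proprioception dynamics of
:mod:`coleokin.ac_model`; on top of the baseline elongation the generator
superposes a traveling wave

    E(s, t) = regr0 * (1 + a * sin(2*pi*(t/Tp - s/(vp*Tp)) + phase))

clipped at zero, tapered smoothly to zero at the basal end of the growth
zone (real elongation profiles decline gradually, and a hard step would
be an artifact), and a differential-growth pulse which forces curvature
at rate ``E * Delta / R`` where ``Delta`` oscillates with a controllable
phase offset ``delta_phase`` relative to the elongation wave.  An
anti-phase offset (pi) produces the negative elongation/curvature-rate
kymograph correlation; in-phase (0) produces a positive one.

Observables (noisy midlines and marker-intensity profiles) are emitted
alongside a :class:`GroundTruth` carrying the exact kymographs and wave
parameters, stored separately so analyses cannot accidentally peek.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ac_model import ACParams, overshoot_predicate, simulate_ac
from .fields import KinematicField
from .geometry import MarkerProfileSeries, MidlineFrame, MidlineSeries

__all__ = [
    "WaveParams",
    "GenConfig",
    "GroundTruth",
    "wave_field",
    "generate_coleoptile_series",
    "generate_cohort",
    "COHORT_DEFAULTS",
]


@dataclass
class WaveParams:
    """A propagating pulse train: period Tp (h), apex-to-base speed vp (mm/h).

    ``amplitude`` is relative for the elongation wave (fraction of the
    baseline REGR, in [0, 1)) and an absolute curvature rate in
    mm^-1 h^-1 for the differential-growth wave.
    """

    Tp: float = 3.0
    vp: float = 12.0
    amplitude: float = 0.4
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.Tp <= 0 or self.vp <= 0:
            raise ValueError("Tp and vp must be positive")

    def __call__(self, s, t):
        """Default traveling-wave form, unit amplitude."""
        return np.sin(2 * np.pi * (t / self.Tp - s / (self.vp * self.Tp)) + self.phase)


def wave_field(params: WaveParams, s_grid, t_grid,
               literal_fig4: bool = False) -> KinematicField:
    """Sample a propagating wave onto an (s, t) kymograph.

    The default form ``sin(2*pi*(t/Tp - s/(vp*Tp)) + phase)`` has temporal
    period exactly Tp and crests traveling apex-to-base at speed vp.  The
    ``literal_fig4`` switch instead emits ``sin(s*Tp*vp + t*Tp)``, the
    idealized-wave formula as printed in the source figure; note that form
    has period 2*pi*Tp and crests moving toward the apex, and is retained
    for documentation only.
    """
    s_grid = np.asarray(s_grid, float)
    t_grid = np.asarray(t_grid, float)
    S, T = np.meshgrid(s_grid, t_grid)
    if literal_fig4:
        vals = np.sin(S * params.Tp * params.vp + T * params.Tp)
    else:
        vals = params(S, T)
    return KinematicField(s_grid, t_grid, vals,
                          np.ones_like(vals, dtype=bool), "wave")


@dataclass
class GenConfig:
    """Configuration of one synthetic coleoptile.

    Defaults state the experimental world being emulated: 24 h at 15-min
    cadence, a 15 mm organ with a 10 mm apical growth zone elongating at
    a baseline 0.036 h^-1 (the measured median, 1e-5 s^-1), elongation
    pulses of relative amplitude 0.4 and differential-growth pulses of
    0.02 mm^-1 h^-1 sharing Tp = 3 h and vp = 12 mm/h, organ radius
    0.5 mm, 8 markers/mm, and 0.02 mm coordinate noise (subpixel tracking
    scale).
    """

    ac: ACParams = field(default_factory=lambda: ACParams(
        beta=0.16, gamma=0.8, L0=15.0, Lgz=10.0, regr0=0.036,
        tilt=np.pi / 2, duration=24.0, dt=0.01, ds=0.05))
    regr_wave: WaveParams = field(default_factory=lambda: WaveParams(
        Tp=3.0, vp=12.0, amplitude=0.4))
    diff_growth_wave: WaveParams = field(default_factory=lambda: WaveParams(
        Tp=3.0, vp=12.0, amplitude=0.02))
    delta_phase: float = np.pi
    radius_R: float = 0.5
    marker_density: float = 8.0
    marker_sigma: float = 0.15
    noise_sd_xy: float = 0.02
    frame_interval: float = 0.25
    profile_step: float = 0.02
    taper_mm: float = 2.0  # basal cosine taper width of the growth zone
    s_step: float = 0.1  # analysis grid for ground-truth kymographs
    sine_graviception: bool = False  # linearized law keeps the overshoot
    # transition of the synthetic world at the classification threshold 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be positive")
        if not (0 <= self.regr_wave.amplitude < 1):
            raise ValueError("REGR wave amplitude must be in [0, 1)")


@dataclass
class GroundTruth:
    """Hidden truth accompanying one generated plant."""

    regr: KinematicField
    curvature_rate: KinematicField
    Tp_regr: float
    vp_regr: float
    Tp_curvrate: float
    vp_curvrate: float
    balance_number: float
    overshoot: bool
    midlines: MidlineSeries  # noise-free
    tip_time: np.ndarray
    tip_angle: np.ndarray

    def scalars(self) -> dict:
        return {
            "Tp_regr": self.Tp_regr,
            "vp_regr": self.vp_regr,
            "Tp_curvrate": self.Tp_curvrate,
            "vp_curvrate": self.vp_curvrate,
            "balance_number": self.balance_number,
            "overshoot": bool(self.overshoot),
        }


def _growth_profile(s, t, cfg: GenConfig):
    """Tapered elongation-rate wave on apex-origin positions, >= 0."""
    p = cfg.ac
    w = cfg.regr_wave
    e = p.regr0 * (1.0 + w.amplitude * w(s, t))
    ramp = np.clip((p.Lgz - np.asarray(s)) / cfg.taper_mm, 0.0, 1.0)
    taper = 0.5 - 0.5 * np.cos(np.pi * ramp)  # 1 apical, 0 past Lgz
    return np.maximum(e * taper, 0.0)


def _delta_profile(s, t, cfg: GenConfig):
    """Dimensionless differential-growth distribution Delta(s, t)."""
    d = cfg.diff_growth_wave
    delta0 = d.amplitude * cfg.radius_R / cfg.ac.regr0
    return delta0 * np.sin(
        2 * np.pi * (t / d.Tp - s / (d.vp * d.Tp))
        + d.phase + cfg.regr_wave.phase + cfg.delta_phase
    )


def generate_coleoptile_series(
    config: GenConfig,
) -> tuple[MidlineSeries, MarkerProfileSeries, GroundTruth]:
    """Simulate one coleoptile and render its observables.

    Returns noisy midlines, marker-intensity profiles (noise-free
    intensities at exactly advected material marker positions), and the
    ground truth.  All randomness derives from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p = cfg.ac

    probe = _growth_profile(np.linspace(0, p.L0, 64), 0.0, cfg)
    if p.regr0 > 0 and probe.max() <= 1e-3 * p.regr0:
        raise ValueError(
            "clipped REGR is (effectively) zero everywhere; no growth possible")

    def regr_hook(s, t):
        return _growth_profile(s, t, cfg)

    def forcing_hook(s, t, e):
        # Eq-8-style coupling; the solver works in the base-origin
        # curvature convention, hence the sign flip of the apex-convention
        # forcing E * Delta / R.
        return -e * _delta_profile(s, t, cfg) / cfg.radius_R

    use_growth = p.regr0 > 0
    state = simulate_ac(
        p, sine=cfg.sine_graviception, store_interval=cfg.frame_interval,
        regr_wave=regr_hook if use_growth else None,
        extra_forcing=forcing_hook,
    )
    # the ground-truth overshoot flag describes the plant's gravitropic
    # class (a function of B), so it comes from a pulse-free companion
    # run: differential-growth pulses wobble the tip by enough to blur
    # the overshoot transition otherwise
    bare = simulate_ac(p, sine=cfg.sine_graviception,
                       store_interval=p.duration)
    true_overshoot = overshoot_predicate(bare.tip_angle_series)

    frames = state.raw_frames
    times = np.array([f[0] for f in frames])
    L_of_t = np.array([f[1][-1] for f in frames])

    # ---- observables -------------------------------------------------
    midline_frames, clean_frames = [], []
    for (t, sig, A, C) in frames:
        # integrate the planar shape from the clamped base at the origin;
        # zenith angle: dx = sin(A), dy = cos(A) moving base -> apex
        dx = np.sin(A)
        dy = np.cos(A)
        x = np.concatenate([[0], np.cumsum((dx[1:] + dx[:-1]) / 2 * np.diff(sig))])
        y = np.concatenate([[0], np.cumsum((dy[1:] + dy[:-1]) / 2 * np.diff(sig))])
        pts = np.column_stack([x, y])[::-1]  # apex first
        # subsample to ~0.1 mm emission spacing
        stride = max(1, int(round(0.1 / (sig[1] - sig[0]))))
        idx = np.unique(np.concatenate([np.arange(0, len(pts), stride), [len(pts) - 1]]))
        pts = pts[idx]
        clean_frames.append(MidlineFrame(t, pts.copy()))
        noisy = pts + rng.normal(0.0, cfg.noise_sd_xy, size=pts.shape)
        midline_frames.append(MidlineFrame(t, noisy))
    midlines = MidlineSeries(midline_frames, cfg.frame_interval)
    true_midlines = MidlineSeries(clean_frames, cfg.frame_interval)

    # ---- markers -----------------------------------------------------
    n_markers = int(round(cfg.marker_density * p.L0))
    s_m0 = np.sort(rng.uniform(0.0, p.L0, n_markers))  # initial apex distance
    amps = rng.uniform(0.5, 1.0, n_markers)
    sig0 = frames[0][1]
    s_nodes0 = (sig0[-1] - sig0)[::-1]  # ascending from apex, initial
    profiles = []
    for (t, sig, A, C) in frames:
        s_nodes = (sig[-1] - sig)[::-1]
        s_m = np.interp(s_m0, s_nodes0, s_nodes)  # material advection map
        L = sig[-1]
        grid = cfg.profile_step * np.arange(int(np.floor(L / cfg.profile_step)) + 1)
        prof = np.zeros(grid.size)
        half_w = int(np.ceil(4 * cfg.marker_sigma / cfg.profile_step))
        centers = np.clip(np.round(s_m / cfg.profile_step).astype(int), 0, grid.size - 1)
        offs = np.arange(-half_w, half_w + 1)
        idx = np.clip(centers[:, None] + offs[None, :], 0, grid.size - 1)
        dist = grid[idx] - s_m[:, None]
        np.add.at(prof, idx,
                  amps[:, None] * np.exp(-0.5 * (dist / cfg.marker_sigma) ** 2))
        profiles.append((grid, prof))
    markers = MarkerProfileSeries(times, profiles, cfg.profile_step)

    # ---- ground truth ------------------------------------------------
    s_grid = cfg.s_step * np.arange(int(np.floor(L_of_t.max() / cfg.s_step + 1e-9)) + 1)
    nt, ns = times.size, s_grid.size
    e_vals = np.full((nt, ns), np.nan)
    cr_vals = np.full((nt, ns), np.nan)
    mask = np.zeros((nt, ns), dtype=bool)
    beta, gamma = p.beta, p.gamma
    for i, (t, sig, A, C) in enumerate(frames):
        m = s_grid <= L_of_t[i] + 1e-9
        mask[i, m] = True
        e_vals[i, m] = _growth_profile(s_grid[m], t, cfg) if use_growth else 0.0
        s_nodes = (sig[-1] - sig)[::-1]
        in_zone = (sig0[-1] - sig0) <= p.Lgz + 1e-12  # material zone, node order
        g = np.sin(A) if cfg.sine_graviception else A
        ac_term = np.where(in_zone, -beta * g - gamma * C, 0.0)
        # apex-origin convention flips the internal curvature sign
        cr_nodes = -ac_term[::-1]
        cr = np.interp(s_grid[m], s_nodes, cr_nodes)
        e_here = _growth_profile(s_grid[m], t, cfg) if use_growth else np.zeros(m.sum())
        cr_vals[i, m] = cr + e_here * _delta_profile(s_grid[m], t, cfg) / cfg.radius_R
    truth_regr = KinematicField(s_grid, times, e_vals, mask, "regr")
    truth_cr = KinematicField(s_grid, times, cr_vals, mask, "curvature_rate")

    truth = GroundTruth(
        regr=truth_regr,
        curvature_rate=truth_cr,
        Tp_regr=cfg.regr_wave.Tp,
        vp_regr=cfg.regr_wave.vp,
        Tp_curvrate=cfg.diff_growth_wave.Tp,
        vp_curvrate=cfg.diff_growth_wave.vp,
        balance_number=p.balance_number,
        overshoot=true_overshoot,
        midlines=true_midlines,
        tip_time=state.tip_time,
        tip_angle=state.tip_angle_series,
    )
    return midlines, markers, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Per-plant parameter distributions for cohort generation (uniform ranges).
COHORT_DEFAULTS = {
    "Tp": (2.5, 3.5),     # h
    "vp": (8.0, 17.0),    # mm/h
    "B": (0.5, 4.0),      # balance number
    "L0": (10.0, 20.0),   # mm
}


def _draw_config(rng: np.random.Generator, group: str, seed: int,
                 dist: dict, base: GenConfig) -> GenConfig:
    Tp = rng.uniform(*dist["Tp"])
    vp = rng.uniform(*dist["vp"])
    B = rng.uniform(*dist["B"])
    L0 = rng.uniform(*dist["L0"])
    tilt = np.pi / 2 if group == "tilted" else 0.0
    delta_phase = np.pi if group == "tilted" else 0.0
    gamma = base.ac.gamma
    Lgz = base.ac.Lgz
    L_eff = min(L0, Lgz)
    ac = replace(base.ac, beta=B * gamma / L_eff, L0=L0, tilt=tilt)
    return replace(
        base,
        ac=ac,
        regr_wave=replace(base.regr_wave, Tp=Tp, vp=vp),
        diff_growth_wave=replace(base.diff_growth_wave, Tp=Tp, vp=vp),
        delta_phase=delta_phase,
        seed=seed,
    )


def cohort_configs(n_straight: int, n_tilted: int, seed: int = 0,
                   distribution: dict | None = None,
                   base: GenConfig | None = None) -> list[tuple[str, str, GenConfig]]:
    """Deterministic per-plant configs: list of (plant_id, group, config)."""
    if n_straight < 1 or n_tilted < 1:
        raise ValueError("need at least one plant per group")
    dist = {**COHORT_DEFAULTS, **(distribution or {})}
    base = base or GenConfig()
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_straight + n_tilted)
    out = []
    groups = ["straight"] * n_straight + ["tilted"] * n_tilted
    for k, group in enumerate(groups):
        cfg = _draw_config(rng, group, int(child_seeds[k] % (2**31)), dist, base)
        out.append((f"plant_{k:03d}", group, cfg))
    return out


def generate_cohort(
    n_straight: int,
    n_tilted: int,
    out_dir: str | Path,
    seed: int = 0,
    distribution: dict | None = None,
    base: GenConfig | None = None,
) -> pd.DataFrame:
    """Write a cohort dataset directory and return its manifest.

    Layout: ``plant_<k>/midline.csv``, ``plant_<k>/markers.csv``,
    ``plant_<k>/truth.json`` (hidden scalar ground truth), and a cohort
    ``manifest.csv`` with columns plant, group.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for plant_id, group, cfg in cohort_configs(
            n_straight, n_tilted, seed, distribution, base):
        pdir = out_dir / plant_id
        pdir.mkdir(exist_ok=True)
        midlines, markers, truth = generate_coleoptile_series(cfg)
        midlines.to_csv(pdir / "midline.csv")
        markers.to_csv(pdir / "markers.csv")
        (pdir / "truth.json").write_text(json.dumps(truth.scalars(), indent=1))
        rows.append({"plant": plant_id, "group": group})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
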