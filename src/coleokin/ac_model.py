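"""Graviception-proprioception (AC) posture dynamics.

The model describes the curvature dynamics of a growing plant organ that
senses both its orientation relative to gravity (graviception, gain
``beta``) and its own curvature (proprioception, gain ``gamma``).  Inside
the growth zone the material curvature evolves as::

    DC/Dt = -beta * sin(A) - gamma * C          (sine law, default)
    DC/Dt = -beta * A      - gamma * C          (linearized variant)

with the base clamped at the imposed tilt and the orientation profile
obtained by integrating curvature from the base.  Curvature is frozen
outside the growth zone.  The entire behaviour is governed by the
dimensionless balance number::

    B = beta * L_eff / gamma,   L_eff = min(L0, Lgz)

Large B (strong graviception) makes the tip overshoot the vertical during
gravitropic recovery; small B leaves a residual lean.  The critical B at
which overshoot first appears is located by bisection in
:func:`critical_balance_number`.

Internally the solver works in a base-origin coordinate (the natural
frame for a clamped base); all exported kymographs follow the package's
apex-origin convention (``s = 0`` at the apex).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .fields import KinematicField

__all__ = [
    "ACParams",
    "ACState",
    "SimulationUnstableError",
    "simulate_ac",
    "overshoot_predicate",
    "critical_balance_number",
]


class SimulationUnstableError(RuntimeError):
    """Curvature diverged; reduce the time step."""


@dataclass
class ACParams:
    """Parameters of an AC-model run.

    beta : graviceptive gain, mm^-1 h^-1 per unit sine of the zenith angle
    gamma : proprioceptive gain, h^-1
    L0 : initial organ length, mm
    Lgz : growth-zone length measured from the apex, mm
    regr0 : baseline relative elongation rate inside the growth zone, h^-1
        (0 disables elongation; the organ then keeps length L0)
    tilt : imposed base zenith angle, rad (pi/2 = horizontal)
    duration : simulated time, h
    dt : solver step, h (default 0.002 / gamma)
    ds : spatial step, mm
    """

    beta: float = 0.2
    gamma: float = 1.0
    L0: float = 12.0
    Lgz: float = 12.0
    regr0: float = 0.0
    tilt: float = np.pi / 2
    duration: float = 24.0
    dt: float | None = None
    ds: float = 0.1

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.L0 <= 0 or self.Lgz <= 0:
            raise ValueError("lengths must be positive")
        if self.dt is None:
            self.dt = 0.002 / self.gamma
        if self.dt * self.gamma >= 0.5:
            raise ValueError("dt * gamma must be < 0.5 for stability")

    @property
    def L_eff(self) -> float:
        """Effective length: the part of the organ able to curve."""
        return min(self.L0, self.Lgz)

    @property
    def balance_number(self) -> float:
        return self.beta * self.L_eff / self.gamma


@dataclass
class ACState:
    """Result of an AC simulation."""

    params: ACParams
    orientation: KinematicField
    curvature: KinematicField
    tip_time: np.ndarray  # h, dense solver-step times
    tip_angle_series: np.ndarray  # A(s=0, t), rad
    raw_frames: list | None = None  # (t, sigma, A, C) per stored frame, base-origin
    balance_number: float = dataclass_field(init=False)

    def __post_init__(self) -> None:
        self.balance_number = self.params.balance_number

    @property
    def min_tip_angle(self) -> float:
        return float(self.tip_angle_series.min())

    @property
    def final_tip_angle(self) -> float:
        return float(self.tip_angle_series[-1])


def simulate_ac(
    params: ACParams,
    sine: bool = True,
    store_interval: float = 0.25,
    regr_wave=None,
    extra_forcing=None,
) -> ACState:
    """Integrate the AC dynamics with explicit Euler time stepping.

    Parameters
    ----------
    params : ACParams
    sine : bool
        Use the sine graviceptive law (default); False linearizes
        ``sin(A) -> A``.
    store_interval : float
        Cadence (h) at which orientation/curvature profiles are stored
        into the output kymographs.  The tip angle is recorded every step.
    regr_wave, extra_forcing : callables, optional
        Hooks used by the synthetic-data generator: ``regr_wave(s, t)``
        returns the REGR profile (h^-1) on the apex-origin node positions
        ``s`` (material points advect accordingly), and
        ``extra_forcing(s, t, regr)`` an additional curvature-rate term
        (mm^-1 h^-1) added inside the growth zone.

    Notes
    -----
    Material nodes are tracked in a Lagrangian frame; with elongation
    enabled the growth zone is the set of material points initially within
    ``Lgz`` of the apex (fixed in material terms).  The steady state of
    the non-growing dynamics satisfies ``gamma * C = -beta * sin(A)``
    inside the growth zone.
    """
    p = params
    dt = p.dt
    n_nodes = max(int(round(p.L0 / p.ds)) + 1, 8)
    # base-origin node arc positions sigma (0 = base); Lagrangian points
    sig = np.linspace(0.0, p.L0, n_nodes)
    C = np.zeros(n_nodes)
    grows = (p.L0 - sig) <= p.Lgz + 1e-12  # material growth zone, apical side
    nt = int(round(p.duration / dt))
    store_every = max(1, int(round(store_interval / dt)))

    tip_t, tip_a = [], []
    frames_t, frames_sig, frames_A, frames_C = [], [], [], []
    div_limit = 1e3 * max(1.0, p.beta / p.gamma)

    t = 0.0
    for step in range(nt + 1):
        A = p.tilt + cumulative_trapezoid(C, sig, initial=0.0)
        tip = A[-1]
        tip_t.append(t)
        tip_a.append(tip)
        if step % store_every == 0:
            frames_t.append(t)
            frames_sig.append(sig.copy())
            frames_A.append(A.copy())
            frames_C.append(C.copy())
        if step == nt:
            break
        g = np.sin(A) if sine else A
        dC = np.where(grows, -p.beta * g - p.gamma * C, 0.0)
        s_apex = sig[-1] - sig  # apex-origin positions of the nodes
        if regr_wave is not None or p.regr0 > 0:
            if regr_wave is not None:
                e = np.asarray(regr_wave(s_apex, t), dtype=float)
            else:
                e = np.where(grows, p.regr0, 0.0)
            e = np.where(grows, np.maximum(e, 0.0), 0.0)
            if extra_forcing is not None:
                dC = dC + np.where(grows, np.asarray(
                    extra_forcing(s_apex, t, e), dtype=float), 0.0)
            # advection: each material point's distance from the apex grows
            # by the integral of REGR between it and the apex
            v_apex = cumulative_trapezoid(e[::-1], s_apex[::-1], initial=0.0)[::-1]
            L_new = sig[-1] + v_apex[0] * dt  # base node carries the full integral
            sig = L_new - (s_apex + v_apex * dt)
            sig[0] = 0.0
        elif extra_forcing is not None:
            dC = dC + np.where(grows, np.asarray(
                extra_forcing(s_apex, t, np.zeros_like(sig)), dtype=float), 0.0)
        C = C + dt * dC
        # instability shows either as diverging curvature or, for the
        # saturating sine law, as the orientation winding through full
        # turns; neither occurs in a physical run
        if (not np.isfinite(C).all() or np.abs(C).max() > div_limit
                or abs(tip) > abs(p.tilt) + 6 * np.pi):
            raise SimulationUnstableError(
                f"solution diverged at t = {t:.3f} h; reduce dt "
                f"(dt * gamma = {dt * p.gamma:.3g})"
            )
        t += dt

    orientation, curvature = _frames_to_fields(
        frames_t, frames_sig, frames_A, frames_C, p.ds
    )
    raw = list(zip(frames_t, frames_sig, frames_A, frames_C))
    return ACState(p, orientation, curvature,
                   np.asarray(tip_t), np.asarray(tip_a), raw_frames=raw)


def _frames_to_fields(times, sigs, As, Cs, ds):
    """Interpolate stored base-origin profiles onto an apex-origin kymograph.

    The exported curvature follows the apex-origin sign convention
    ``C = dA/ds`` with s measured from the apex, i.e. the negative of the
    base-origin curvature used internally by the solver.
    """
    L_max = max(s[-1] for s in sigs)
    s_grid = ds * np.arange(int(np.floor(L_max / ds + 1e-9)) + 1)
    t_grid = np.asarray(times)
    nt, ns = t_grid.size, s_grid.size
    A_vals = np.full((nt, ns), np.nan)
    C_vals = np.full((nt, ns), np.nan)
    mask = np.zeros((nt, ns), dtype=bool)
    for i, (sig, A, C) in enumerate(zip(sigs, As, Cs)):
        L = sig[-1]
        s_apex = (L - sig)[::-1]  # ascending from apex
        m = s_grid <= L + 1e-9
        A_vals[i, m] = np.interp(s_grid[m], s_apex, A[::-1])
        C_vals[i, m] = np.interp(s_grid[m], s_apex, -C[::-1])
        mask[i, m] = True
    return (
        KinematicField(s_grid, t_grid, A_vals, mask, "orientation"),
        KinematicField(s_grid, t_grid, C_vals, mask, "curvature"),
    )


def overshoot_predicate(tip_angle_series: np.ndarray, delta: float = 0.02) -> bool:
    """True iff the tip passes beyond the vertical by more than ``delta``.

    Strict inequality: a series whose minimum equals exactly ``-delta``
    does not count as an overshoot.
    """
    series = np.asarray(tip_angle_series, dtype=float)
    if series.size == 0:
        raise ValueError("empty tip-angle series")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return bool(series.min() < -delta)


def _overshoots_at(B: float, template: ACParams, sine: bool, delta: float) -> bool:
    p = ACParams(
        beta=B * template.gamma / template.L_eff,
        gamma=template.gamma,
        L0=template.L0,
        Lgz=template.Lgz,
        regr0=0.0,
        tilt=template.tilt,
        duration=template.duration,
        dt=template.dt,
        ds=template.ds,
    )
    state = simulate_ac(p, sine=sine, store_interval=p.duration)
    return overshoot_predicate(state.tip_angle_series, delta)


def critical_balance_number(
    params_template: ACParams | None = None,
    B_low: float = 0.5,
    B_high: float = 10.0,
    tol: float = 0.05,
    sine: bool = False,
    delta: float = 0.0,
    prescan: int = 12,
) -> float:
    """Critical balance number B_c separating overshoot from no overshoot.

    Bisection on B (varying beta at fixed gamma and L_eff) on a non-growing
    organ tilted per the template (default pi/2).  A coarse pre-scan first
    asserts that the overshoot indicator is non-decreasing in B and
    tightens the bracket.

    By default the graviceptive term is linearized (``sine=False``) and
    the transition is the strict sign change of the minimum tip angle
    (``delta=0``): the linear small-deviation analysis is what defines the
    classical overshoot threshold, and simulated tip-angle minima are
    smooth so no guard band is needed.  Pass ``sine=True`` and/or a
    positive ``delta`` for the alternative readings; see the methods note
    for the numerical difference.
    """
    if params_template is None:
        params_template = ACParams(duration=40.0, L0=1.0, Lgz=1.0, gamma=1.0,
                                   beta=1.0, tilt=np.pi / 2, ds=1.0 / 200)
    if not (B_low < B_high):
        raise ValueError("need B_low < B_high")
    flags = []
    grid = np.linspace(B_low, B_high, prescan)
    for B in grid:
        flags.append(_overshoots_at(B, params_template, sine, delta))
    if flags[0] or not flags[-1]:
        raise ValueError(
            f"invalid bracket: overshoot at B_low is {flags[0]}, "
            f"at B_high is {flags[-1]}"
        )
    if any(a and not b for a, b in zip(flags, flags[1:])):
        raise RuntimeError("overshoot indicator not monotone over pre-scan grid")
    k = int(np.argmax(flags))  # first True
    lo, hi = grid[k - 1], grid[k]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _overshoots_at(mid, params_template, sine, delta):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
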