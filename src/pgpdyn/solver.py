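"""Numerical integration of the coupled transport + MV system.

Operator-split explicit scheme per step:

1. conservative finite-volume upwind advection of each density with its
   phenotype-drift velocity (optional minmod/MUSCL limiter), zero-flux
   boundaries (the velocities vanish at the upper boundary by
   construction, and there is no inflow at the lower one);
2. explicit Euler reaction update: nonlocal birth integral, crowding decay
   and therapy losses;
3. explicit Euler update of the MV pool, clipped at zero.

The step size obeys both ``dt_max`` and the advective CFL bound
``dt <= cfl * dx / max|v|``; :func:`simulate` additionally lands exactly on
every schedule switch time and recording time, so piecewise-constant drug
schedules are resolved without smearing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import quadrature_weights
from .kinetics import (
    birth_operator,
    crowding_decay,
    induction_velocity,
    mv_flux,
    therapy_rate,
    transfer_velocity,
)
from .params import ProcessParameters
from .schedule import DrugSchedule
from .state import SystemState, total_cells

__all__ = ["SolverConfig", "Trajectory", "step", "simulate"]

_NEG_TOL = -1e-12


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the transport solver.

    ``dt_max`` caps the step (h); ``cfl`` in (0, 0.95] bounds the advective
    Courant number; ``quadrature`` selects the grid quadrature rule;
    ``limiter`` enables second-order MUSCL reconstruction with the minmod
    limiter; ``record_every`` is the trajectory recording cadence (h).
    """

    dt_max: float = 0.1
    cfl: float = 0.9
    quadrature: str = "midpoint"
    limiter: str = "none"
    record_every: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cfl <= 0.95:
            raise ValueError(f"cfl must be in (0, 0.95], got {self.cfl}")
        if self.dt_max <= 0:
            raise ValueError("dt_max must be > 0")
        if self.record_every <= 0:
            raise ValueError("record_every must be > 0")
        if self.limiter not in ("none", "minmod"):
            raise ValueError(f"unknown limiter: {self.limiter!r}")
        if self.quadrature not in ("midpoint", "trapezoid", "simpson"):
            raise ValueError(f"unknown quadrature: {self.quadrature!r}")


@dataclass
class Trajectory:
    """Recorded simulation output.

    ``totals`` has shape ``(2, len(times))`` with ``totals[i-1, k]`` the
    cell number of class i at ``times[k]``; ``states`` holds deep snapshots
    at the recording times.
    """

    times: np.ndarray
    states: list[SystemState]
    totals: np.ndarray
    M_series: np.ndarray

    def total(self) -> np.ndarray:
        """Total cell number N1 + N2 at each recorded time."""
        return self.totals.sum(axis=0)


def _edge_velocity(state: SystemState, C: float, p: ProcessParameters) -> np.ndarray:
    """Drift velocity of the sensitive class at the cell edges (>= 0)."""
    edges = state.grid.edges
    v = transfer_velocity(edges, state.M, C, p, state.grid) + induction_velocity(
        edges, C, p, state.grid
    )
    return np.asarray(v, dtype=float)


def _advect(u: np.ndarray, v_edge: np.ndarray, dt: float, dx: float, limiter: str) -> np.ndarray:
    """One conservative upwind step for nonnegative edge velocities.

    Interior flux at edge j+1/2 is ``v * u_face`` with the upwind (left)
    face value, optionally corrected by a minmod-limited slope; boundary
    fluxes are zero.
    """
    n = len(u)
    flux = np.zeros(n + 1)
    if limiter == "minmod":
        du_lo = np.empty(n)
        du_hi = np.empty(n)
        du_lo[0] = 0.0
        du_lo[1:] = u[1:] - u[:-1]
        du_hi[:-1] = u[1:] - u[:-1]
        du_hi[-1] = 0.0
        slope = np.where(
            du_lo * du_hi > 0.0, np.sign(du_lo) * np.minimum(np.abs(du_lo), np.abs(du_hi)), 0.0
        )
        face = u + 0.5 * slope * (1.0 - v_edge[1:] * dt / dx)
        flux[1:-1] = v_edge[1:-1] * face[:-1]
    else:
        flux[1:-1] = v_edge[1:-1] * u[:-1]
    return u - (dt / dx) * (flux[1:] - flux[:-1])


def _check_density(u: np.ndarray, term: str, t: float) -> np.ndarray:
    if not np.all(np.isfinite(u)):
        raise FloatingPointError(f"non-finite density after {term} at t={t:.3f} h")
    if np.min(u) < _NEG_TOL:
        raise FloatingPointError(
            f"negative density ({np.min(u):.3e}) after {term} at t={t:.3f} h"
        )
    return np.maximum(u, 0.0)


def step(
    state: SystemState,
    schedule: DrugSchedule,
    p: ProcessParameters,
    cfg: SolverConfig,
    dt: float,
) -> SystemState:
    """Advance the system by one operator-split step of size ``dt`` (h).

    Raises on CFL violation and on non-finite or significantly negative
    densities (tiny negatives below 1e-12 in magnitude are clipped).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    grid = state.grid
    dx = grid.dx
    C = schedule.concentration(state.t)

    # --- (i) conservative advection (sensitive class only by default:
    # resistant cells neither take up MVs nor respond to induction)
    v_edge = _edge_velocity(state, C, p)
    vmax = float(np.max(np.abs(v_edge)))
    if vmax > 0 and dt > cfg.cfl * dx / vmax * (1.0 + 1e-9):
        raise ValueError(
            f"CFL violation: dt={dt:.4g} h exceeds {cfg.cfl * dx / vmax:.4g} h "
            f"(max |v|={vmax:.4g} activity/h) at t={state.t:.3f} h"
        )
    u1 = _advect(state.u1.values, v_edge, dt, dx, cfg.limiter)
    u1 = _check_density(u1, "advection", state.t)
    u2 = state.u2.values.copy()

    # --- (ii) reaction: birth integral, crowding, therapy
    g1, g2 = crowding_decay(state, p)
    T = therapy_rate(grid.centers, C, p)
    A1 = birth_operator(grid, 1, p, cfg.quadrature)
    A2 = birth_operator(grid, 2, p, cfg.quadrature)
    u1 = u1 + dt * (A1 @ u1 - (g1 + T) * u1)
    u2 = u2 + dt * (A2 @ u2 - (g2 + T) * u2)
    u1 = _check_density(u1, "reaction (u1)", state.t)
    u2 = _check_density(u2, "reaction (u2)", state.t)

    # --- (iii) MV pool
    M = state.M + dt * mv_flux(state, p)
    if not np.isfinite(M):
        raise FloatingPointError(f"non-finite MV concentration at t={state.t:.3f} h")
    M = max(M, 0.0)

    return SystemState.from_arrays(grid, u1, u2, M=M, t=state.t + dt)


def simulate(
    scenario,
    p: ProcessParameters,
    cfg: SolverConfig | None = None,
) -> Trajectory:
    """Integrate an experiment scenario to its horizon.

    Deterministic given inputs.  Records every ``cfg.record_every`` hours
    (plus the initial time and the horizon).  Step sizes are chosen as
    ``min(dt_max, cfl * dx / max|v|)`` and adjusted to land exactly on
    schedule switch times and recording times.
    """
    cfg = cfg or SolverConfig()
    schedule: DrugSchedule = scenario.schedule
    horizon = float(scenario.horizon)
    state = scenario.initial_state(p, cfg)

    rec_times = list(np.arange(0.0, horizon + 1e-9, cfg.record_every))
    if not rec_times or rec_times[-1] < horizon - 1e-9:
        rec_times.append(horizon)
    breakpoints = sorted(
        {t for t in schedule.switch_times() if 0.0 < t < horizon}
        | {t for t in rec_times if t > 0.0}
    )

    times = [state.t]
    states = [state.copy()]
    totals = [total_cells(state, cfg.quadrature)]
    M_series = [state.M]

    rec_set = {round(t, 9) for t in rec_times}
    for t_next in breakpoints:
        while state.t < t_next - 1e-9:
            v_edge = _edge_velocity(state, schedule.concentration(state.t), p)
            vmax = float(np.max(np.abs(v_edge)))
            dt_cfl = cfg.cfl * state.grid.dx / vmax if vmax > 0 else np.inf
            dt = min(cfg.dt_max, dt_cfl, t_next - state.t)
            try:
                state = step(state, schedule, p, cfg, dt)
            except FloatingPointError as err:
                raise FloatingPointError(f"simulate failed: {err}") from err
        state.t = t_next  # kill 1e-9-scale drift so recording times stay exact
        if round(t_next, 9) in rec_set:
            times.append(state.t)
            states.append(state.copy())
            totals.append(total_cells(state, cfg.quadrature))
            M_series.append(state.M)

    return Trajectory(
        times=np.asarray(times),
        states=states,
        totals=np.asarray(totals).T,
        M_series=np.asarray(M_series),
    )
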