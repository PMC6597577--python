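"""Synthetic flow-cytometry event samples and impedance growth curves.

The generator emulates the statistical structure of the wet-lab readouts
the analysis consumes: per-cell P-gp activity values with multinomial
sampling noise at the cytometer's event floor (2e4 events per sample),
and xCELLigence-like growth curves (impedance proxy proportional to cell
number, sampled every 30 min, multiplicative Gaussian noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sst

from .experiments import ExperimentScenario, make_mixture_scenario
from .grid import ActivityGrid, quadrature_weights
from .params import ProcessParameters, default_params
from .solver import SolverConfig, simulate
from .state import SystemState

__all__ = [
    "EventSample",
    "GrowthCurve",
    "sample_events",
    "basal_sample",
    "generate_growth_curve",
]

#: Label value for events whose class is unknown.
UNKNOWN_LABEL = 0


@dataclass
class EventSample:
    """Per-cell activity values emulating a flow-cytometry export.

    ``labels`` holds the constitutive class per event (1, 2, or 0 for
    unknown).  ``condition`` is a free-text sample annotation; ``seed`` is
    the generator seed that produced the sample (-1 for external data).
    """

    activities: np.ndarray
    labels: np.ndarray
    condition: str = ""
    seed: int = -1

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.activities.ndim != 1 or self.labels.shape != self.activities.shape:
            raise ValueError("activities and labels must be 1-D and congruent")
        if not np.all(np.isin(self.labels, (UNKNOWN_LABEL, 1, 2))):
            raise ValueError("labels must be 0 (unknown), 1 or 2")

    @property
    def n_events(self) -> int:
        return len(self.activities)


@dataclass
class GrowthCurve:
    """Impedance-proxy growth curve (arbitrary units, 0.5 h cadence)."""

    times: np.ndarray
    values: np.ndarray
    dose: float = 0.0
    seed: int = -1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must be congruent")
        if len(self.times) and not np.isclose(self.times[0], 0.0):
            raise ValueError("growth-curve times must start at 0")
        if len(self.times) > 1 and not np.allclose(np.diff(self.times), 0.5):
            raise ValueError("growth-curve spacing must be 0.5 h")


def sample_events(
    state: SystemState,
    n_events: int = 20_000,
    seed: int = 0,
    condition: str = "",
) -> EventSample:
    """Draw a fixed-size cytometer aliquot from a system state.

    Event activities are i.i.d. draws from the normalized mixture density
    (placed at the grid cell centers); per-event class labels are drawn
    proportionally to the class densities at the drawn cell.  Deterministic
    given ``seed``.
    """
    grid = state.grid
    w = quadrature_weights(grid)
    mass = (state.u1.values + state.u2.values) * w
    total = float(mass.sum())
    if total <= 0:
        raise ValueError("cannot sample events from an empty state")
    rng = np.random.default_rng(seed)
    idx = rng.choice(grid.n_bins, size=n_events, p=mass / total)
    mix = state.u1.values + state.u2.values
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = np.where(mix > 0, state.u2.values / np.where(mix > 0, mix, 1.0), 0.0)
    labels = np.where(rng.random(n_events) < p2[idx], 2, 1)
    return EventSample(
        activities=grid.centers[idx],
        labels=labels,
        condition=condition,
        seed=seed,
    )


def basal_sample(
    index: int,
    n_events: int = 20_000,
    seed: int = 0,
    p: ProcessParameters | None = None,
    grid: ActivityGrid | None = None,
) -> EventSample:
    """Events from the basal Gaussian of one class, truncated to the domain."""
    p = p or default_params()
    grid = grid or ActivityGrid()
    b = {1: p.b1, 2: p.b2}[index]
    a_, b_ = (grid.x_min - b) / p.s_basal, (grid.x_max - b) / p.s_basal
    rng = np.random.default_rng(seed)
    x = _sst.truncnorm.rvs(a_, b_, loc=b, scale=p.s_basal, size=n_events, random_state=rng)
    return EventSample(
        activities=x,
        labels=np.full(n_events, index, dtype=int),
        condition=f"basal_{index}",
        seed=seed,
    )


def generate_growth_curve(
    dose: float,
    p: ProcessParameters | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_init: float = 4.0e3,
    horizon: float = 96.0,
    cfg: SolverConfig | None = None,
    scenario: ExperimentScenario | None = None,
) -> GrowthCurve:
    """Noisy impedance-proxy growth curve of a sensitive-only culture.

    Simulates 4e3 initially sensitive cells under a constant ``dose`` (nM),
    converts the total cell number to an impedance proxy (proportional map,
    normalized to 1 at seeding) sampled every 0.5 h, and applies
    multiplicative Gaussian noise of relative sd ``noise_sd``.  With
    ``noise_sd=0`` the curve equals the deterministic simulation exactly.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    p = p or default_params()
    cfg = cfg or SolverConfig(record_every=0.5)
    if cfg.record_every != 0.5:
        cfg = SolverConfig(
            dt_max=cfg.dt_max,
            cfl=cfg.cfl,
            quadrature=cfg.quadrature,
            limiter=cfg.limiter,
            record_every=0.5,
        )
    scenario = scenario or make_mixture_scenario(
        (1, 0), dose=dose, n_init=n_init, horizon=horizon
    )
    traj = simulate(scenario, p, cfg)
    values = traj.total() / traj.total()[0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + noise_sd * rng.standard_normal(len(values)))
    return GrowthCurve(times=traj.times, values=values, dose=dose, seed=seed)
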