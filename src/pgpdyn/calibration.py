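"""Distribution-matching calibration of the process parameters.

The fit minimizes a combined loss over experimental conditions:
1-Wasserstein distance between observed event samples and the simulated
mixture density at matching times, plus (weighted) squared relative
residuals on growth curves.  Optimization is derivative-free (Nelder-Mead
via lmfit) with bounded parameters.

Because many parameters act on overlapping observables, the recommended
identification is staged (:func:`staged_fit`):

1. ``growth``    — proliferation rate from drug-free growth curves;
2. ``therapy``   — kill amplitude and half-maximal dose from the dose
   ladder of growth curves;
3. ``reversion`` — per-division reversion fraction from the sorted-cell
   relaxation series;
4. ``transfer``  — MV-transfer amplitudes (without/with drug) from the
   medium-exchange event samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy import stats as _sst

from .experiments import (
    ExperimentScenario,
    conditioned_medium_mv_load,
    make_medium_exchange_scenario,
    make_mixture_scenario,
    make_sorting_scenario,
)
from .grid import ActivityGrid, quadrature_weights
from .params import ProcessParameters, default_params
from .solver import SolverConfig, Trajectory, simulate
from .state import SystemState
from .synth import EventSample, GrowthCurve

__all__ = [
    "histogram_distance",
    "l2_histogram_distance",
    "FitDataset",
    "FitResult",
    "fit",
    "CalibrationData",
    "staged_fit",
]


def histogram_distance(obs: EventSample, sim: SystemState) -> float:
    """1-Wasserstein distance between an event sample and a simulated state.

    Compares the empirical CDF of the observed activities with the CDF of
    the normalized simulated mixture density (u1 + u2) / N on the grid.
    Zero iff the distributions coincide on the grid; invariant to event
    order.
    """
    if obs.n_events == 0:
        raise ValueError("observed sample is empty")
    grid = sim.grid
    mass = sim.mixture_density() * quadrature_weights(grid)
    total = mass.sum()
    if total <= 0:
        raise ValueError("simulated state is empty")
    return float(
        _sst.wasserstein_distance(obs.activities, grid.centers, None, mass / total)
    )


def l2_histogram_distance(obs: EventSample, sim: SystemState) -> float:
    """Alternative fit criterion: L2 distance between normalized histograms.

    The observed events are binned onto the simulation grid; both
    histograms are normalized to unit mass before the L2 norm.
    """
    if obs.n_events == 0:
        raise ValueError("observed sample is empty")
    grid = sim.grid
    w = quadrature_weights(grid)
    hist, _ = np.histogram(obs.activities, bins=grid.edges)
    h_obs = hist / (obs.n_events * grid.dx)
    mix = sim.mixture_density()
    h_sim = mix / float(w @ mix)
    return float(np.sqrt(np.sum((h_obs - h_sim) ** 2) * grid.dx))


_DISTANCES = {"wasserstein": histogram_distance, "l2": l2_histogram_distance}


@dataclass
class FitDataset:
    """Observations attached to one constructible scenario.

    ``events`` is a list of ``(time_h, EventSample)`` pairs; ``growth`` an
    optional growth curve (relative impedance values); ``growth_weight``
    scales the growth-curve term of the loss.
    """

    scenario: ExperimentScenario
    events: list[tuple[float, EventSample]] = field(default_factory=list)
    growth: GrowthCurve | None = None
    growth_weight: float = 1.0


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    params: ProcessParameters
    loss: float
    n_evals: int
    converged: bool
    seed: int
    free_names: list[str]


def _default_bounds(name: str) -> tuple[float, float]:
    """Parameter bounds: rates in [0, 10x calibrated default], lambda in (0.01, 1]."""
    if name == "lambda_rev":
        return 0.01, 1.0
    ref = getattr(default_params(), name)
    hi = 10.0 * ref if ref > 0 else 1.0
    return 0.0, hi


def _states_at(traj: Trajectory, times: list[float]) -> list[SystemState]:
    out = []
    for t in times:
        k = int(np.argmin(np.abs(traj.times - t)))
        if abs(traj.times[k] - t) > 0.51 * np.max(np.diff(traj.times, prepend=0.0)):
            raise ValueError(f"no recorded state near t={t} h")
        out.append(traj.states[k])
    return out


def _loss(
    p: ProcessParameters,
    datasets: list[FitDataset],
    cfg: SolverConfig,
    distance: str,
) -> float:
    dist = _DISTANCES[distance]
    total = 0.0
    for ds in datasets:
        needs_events = bool(ds.events)
        if not needs_events and ds.growth is None:
            continue
        traj = simulate(ds.scenario, p, cfg)
        for t_obs, sample in ds.events:
            (state,) = _states_at(traj, [t_obs])
            total += dist(sample, state)
        if ds.growth is not None:
            rel = np.interp(ds.growth.times, traj.times, traj.total())
            rel = rel / rel[0]
            total += ds.growth_weight * float(
                np.mean((rel / np.maximum(ds.growth.values, 1e-12) - 1.0) ** 2)
            )
    if not np.isfinite(total):
        raise FloatingPointError("non-finite calibration loss")
    return total


def fit(
    datasets: list[FitDataset],
    free_names: list[str],
    init: ProcessParameters | None = None,
    seed: int = 0,
    cfg: SolverConfig | None = None,
    distance: str = "wasserstein",
    bounds: dict[str, tuple[float, float]] | None = None,
    max_evals: int = 400,
) -> FitResult:
    """Fit the named free parameters to the datasets.

    Derivative-free bounded local optimization (Nelder-Mead); all other
    parameters stay at ``init``.  Deterministic given ``init`` and the
    datasets; ``seed`` is recorded for provenance.
    """
    if not free_names:
        raise ValueError("free_names must be nonempty")
    if distance not in _DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; choose from {sorted(_DISTANCES)}")
    init = init or default_params()
    cfg = cfg or SolverConfig()
    init_loss = _loss(init, datasets, cfg, distance)

    lp = lmfit.Parameters()
    for name in free_names:
        lo, hi = (bounds or {}).get(name, _default_bounds(name))
        value = float(np.clip(getattr(init, name), lo if lo > 0 else 1e-12, hi))
        lp.add(name, value=value, min=lo, max=hi)

    def objective(params: lmfit.Parameters) -> float:
        trial = init.replace(**{n: float(params[n].value) for n in free_names})
        return _loss(trial, datasets, cfg, distance)

    res = lmfit.minimize(
        objective, lp, method="nelder", options={"maxfev": max_evals, "xatol": 1e-4, "fatol": 1e-12}
    )
    fitted = init.replace(**{n: float(res.params[n].value) for n in free_names})
    final_loss = _loss(fitted, datasets, cfg, distance)
    if final_loss > init_loss:  # descent contract: never worse than the start
        fitted, final_loss = init, init_loss
    return FitResult(
        params=fitted,
        loss=final_loss,
        n_evals=int(res.nfev),
        converged=bool(res.success),
        seed=seed,
        free_names=list(free_names),
    )


# ---------------------------------------------------------------------------
# staged identification


@dataclass
class CalibrationData:
    """Data bundle for the staged identification protocol.

    ``growth_curves``: drug-free and dose-ladder growth curves (relative
    impedance, 4e3-cell seeding).  ``sorting_series``: ``(time_h, sample)``
    pairs from the sorted-high reversibility assay.  ``medium_exchange``:
    48 h event samples keyed by condition, using keys ``"cm"``
    (conditioned medium, no drug) and ``"dox_cm"`` (conditioned medium,
    50 nM DOX).
    """

    growth_curves: list[GrowthCurve] = field(default_factory=list)
    sorting_series: list[tuple[float, EventSample]] = field(default_factory=list)
    medium_exchange: dict[str, EventSample] = field(default_factory=dict)
    growth_n_init: float = 4.0e3
    sorting_n_init: float = 2.0e5


def staged_fit(
    data: CalibrationData,
    init: ProcessParameters | None = None,
    seed: int = 0,
    cfg: SolverConfig | None = None,
    grid: ActivityGrid | None = None,
    distance: str = "wasserstein",
) -> dict[str, FitResult]:
    """Run the staged identification; returns one FitResult per stage.

    Each stage starts from the previous stage's parameter set, limiting
    non-identifiability from parameters that act on the same observables.
    Stages without data are skipped.
    """
    p = init or default_params()
    grid = grid or ActivityGrid()
    results: dict[str, FitResult] = {}

    drug_free = [g for g in data.growth_curves if g.dose == 0]
    dosed = [g for g in data.growth_curves if g.dose > 0]

    if drug_free:
        datasets = [
            FitDataset(
                scenario=make_mixture_scenario(
                    (1, 0), dose=0.0, n_init=data.growth_n_init,
                    horizon=float(g.times[-1]), grid=grid,
                ),
                growth=g,
            )
            for g in drug_free
        ]
        results["growth"] = fit(datasets, ["r_max_1"], p, seed, cfg, distance)
        p = results["growth"].params

    if dosed:
        datasets = [
            FitDataset(
                scenario=make_mixture_scenario(
                    (1, 0), dose=g.dose, n_init=data.growth_n_init,
                    horizon=float(g.times[-1]), grid=grid,
                ),
                growth=g,
            )
            for g in dosed
        ]
        results["therapy"] = fit(datasets, ["delta_max", "C50"], p, seed, cfg, distance)
        p = results["therapy"].params

    if data.sorting_series:
        horizon = max(t for t, _ in data.sorting_series)
        scenario = make_sorting_scenario(
            n_init=data.sorting_n_init, horizon=horizon, grid=grid
        )
        datasets = [FitDataset(scenario=scenario, events=list(data.sorting_series))]
        results["reversion"] = fit(datasets, ["lambda_rev"], p, seed, cfg, distance)
        p = results["reversion"].params

    if data.medium_exchange:
        # the conditioned-medium MV load does not depend on the transfer
        # amplitudes, so resolve the nested donor simulation once
        m_cm = conditioned_medium_mv_load(p, cfg, grid=grid)
        for key, free in (("cm", "kappa0"), ("dox_cm", "kappaD")):
            if key not in data.medium_exchange:
                continue
            sample = data.medium_exchange[key]
            scenario = replace(
                make_medium_exchange_scenario(dox=(key == "dox_cm"), conditioned=True, grid=grid),
                M0=m_cm,
            )
            datasets = [FitDataset(scenario=scenario, events=[(scenario.horizon, sample)])]
            results[f"transfer_{free}"] = fit(datasets, [free], p, seed, cfg, distance)
            p = results[f"transfer_{free}"].params

    return results
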