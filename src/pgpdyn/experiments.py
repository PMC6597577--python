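"""The four in vitro experiment designs as reproducible scenarios.

* growth/mixture assays: sensitive and resistant cells seeded at ratios
  1:0, 0:1, 1:1, 3:1 or 7:1, with or without a constant drug dose;
* medium exchange: sensitive-only cultures grown in fresh or conditioned
  medium (the conditioned-medium MV load is obtained by a nested
  simulation of a resistant-only culture, not a free parameter);
* sorting/reversibility: sensitive cells isolated at the resistant
  (high-P-gp) profile and left in fresh drug-free medium;
* treatment protocols 1-3: 240 h schedules with 120 h of total drug
  exposure each, differing only in timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import ActivityGrid
from .kinetics import equilibrium_density
from .params import ProcessParameters, default_params
from .schedule import DrugSchedule, constant_schedule
from .solver import SolverConfig, Trajectory, simulate
from .state import SystemState

__all__ = [
    "ALLOWED_RATIOS",
    "ExperimentScenario",
    "make_mixture_scenario",
    "make_medium_exchange_scenario",
    "make_sorting_scenario",
    "make_protocol_schedule",
    "GrowthDelayResult",
    "growth_delay",
    "response_amplitude",
]

#: Seeding ratios (sensitive : resistant) used in the mixture experiments.
ALLOWED_RATIOS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (3, 1), (7, 1))

#: Sentinel for a conditioned-medium initial MV load (resolved by nested
#: simulation of a 24 h resistant-only culture when the scenario is built
#: into an initial state).
CONDITIONED = "conditioned"


@dataclass(frozen=True)
class ExperimentScenario:
    """Declarative description of one in vitro experiment.

    ``M0`` is either a number (MV units) or the sentinel ``"conditioned"``;
    ``init_u1_shape`` is ``"basal"`` (sensitive basal profile) or
    ``"sorted_high"`` (sensitive cells starting at the *resistant* basal
    profile, as obtained by sorting).
    """

    name: str
    init_ratio: tuple[int, int] = (1, 0)
    n_init: float = 2.0e4
    init_u1_shape: str = "basal"
    M0: float | str = 0.0
    schedule: DrugSchedule = field(default_factory=lambda: constant_schedule(0.0, 96.0))
    horizon: float = 96.0
    grid: ActivityGrid = field(default_factory=ActivityGrid)

    def __post_init__(self) -> None:
        if self.n_init <= 0:
            raise ValueError("n_init must be > 0")
        if isinstance(self.M0, str):
            if self.M0 != CONDITIONED:
                raise ValueError(f"M0 must be a number or {CONDITIONED!r}")
        elif self.M0 < 0:
            raise ValueError("M0 must be >= 0")
        if self.init_u1_shape not in ("basal", "sorted_high"):
            raise ValueError("init_u1_shape must be 'basal' or 'sorted_high'")
        if tuple(self.init_ratio) not in ALLOWED_RATIOS:
            raise ValueError(
                f"unknown ratio {self.init_ratio}; allowed sensitive:resistant "
                f"ratios are {', '.join('%d:%d' % r for r in ALLOWED_RATIOS)}"
            )
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    def initial_masses(self) -> tuple[float, float]:
        s, r = self.init_ratio
        return self.n_init * s / (s + r), self.n_init * r / (s + r)

    def initial_state(
        self, p: ProcessParameters, cfg: SolverConfig | None = None
    ) -> SystemState:
        """Build the initial system state for the given parameters.

        Densities start at the class equilibrium (basal) profiles scaled to
        the ratio masses; a ``sorted_high`` sensitive class starts at the
        *resistant* profile instead.  A conditioned-medium M0 is resolved
        by :func:`conditioned_medium_mv_load`.
        """
        n1, n2 = self.initial_masses()
        shape1 = equilibrium_density(
            self.grid, 2 if self.init_u1_shape == "sorted_high" else 1, p
        )
        shape2 = equilibrium_density(self.grid, 2, p)
        M0 = self.M0
        if M0 == CONDITIONED:
            M0 = conditioned_medium_mv_load(p, cfg, grid=self.grid)
        return SystemState.from_arrays(
            self.grid, n1 * shape1, n2 * shape2, M=float(M0), t=0.0
        )


def make_mixture_scenario(
    ratio: tuple[int, int] | str,
    dose: float = 0.0,
    n_init: float = 2.0e4,
    horizon: float = 96.0,
    grid: ActivityGrid | None = None,
) -> ExperimentScenario:
    """Mixture assay: basal classes seeded at ``ratio``, constant ``dose`` (nM)."""
    if isinstance(ratio, str):
        try:
            s, r = (int(part) for part in ratio.split(":"))
        except ValueError as err:
            raise ValueError(f"cannot parse ratio {ratio!r}; use e.g. '3:1'") from err
        ratio = (s, r)
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return ExperimentScenario(
        name=f"mixture_{ratio[0]}to{ratio[1]}_dox{dose:g}",
        init_ratio=tuple(ratio),
        n_init=n_init,
        schedule=constant_schedule(dose, horizon),
        horizon=horizon,
        grid=grid or ActivityGrid(),
    )


def conditioned_medium_mv_load(
    p: ProcessParameters | None = None,
    cfg: SolverConfig | None = None,
    grid: ActivityGrid | None = None,
    culture_hours: float = 24.0,
    n_init: float = 2.0e4,
) -> float:
    """MV concentration of a conditioned medium.

    Simulates a resistant-only culture for ``culture_hours`` starting from
    a fresh medium (M = 0) and returns the final MV concentration — the
    conditioned-medium load is therefore fixed by the parameter set rather
    than being a free knob.
    """
    p = p or default_params()
    donor = ExperimentScenario(
        name="cm_donor",
        init_ratio=(0, 1),
        n_init=n_init,
        M0=0.0,
        schedule=constant_schedule(0.0, culture_hours),
        horizon=culture_hours,
        grid=grid or ActivityGrid(),
    )
    traj = simulate(donor, p, cfg)
    return float(traj.M_series[-1])


def make_medium_exchange_scenario(
    dox: bool,
    conditioned: bool,
    n_init: float = 2.0e4,
    horizon: float = 48.0,
    dose: float = 50.0,
    grid: ActivityGrid | None = None,
) -> ExperimentScenario:
    """Medium-exchange assay: sensitive-only culture, 48 h, four conditions.

    ``conditioned`` selects a conditioned medium (initial MV load from a
    24 h resistant-only donor culture); ``dox`` adds a constant 50 nM dose.
    """
    label = ("dox" if dox else "nodox") + ("_cm" if conditioned else "_fresh")
    return ExperimentScenario(
        name=f"medium_exchange_{label}",
        init_ratio=(1, 0),
        n_init=n_init,
        M0=CONDITIONED if conditioned else 0.0,
        schedule=constant_schedule(dose if dox else 0.0, horizon),
        horizon=horizon,
        grid=grid or ActivityGrid(),
    )


def make_sorting_scenario(
    n_init: float = 2.0e5,
    horizon: float = 240.0,
    grid: ActivityGrid | None = None,
) -> ExperimentScenario:
    """Reversibility assay: sorted high-P-gp sensitive cells in fresh medium.

    The sensitive class starts at the resistant basal profile (sorted cells
    and resistant cells are initially indistinguishable), with no drug and
    no MVs, monitored for ten days.
    """
    return ExperimentScenario(
        name="sorted_high_pgp",
        init_ratio=(1, 0),
        n_init=n_init,
        init_u1_shape="sorted_high",
        M0=0.0,
        schedule=constant_schedule(0.0, horizon),
        horizon=horizon,
        grid=grid or ActivityGrid(),
    )


_PROTOCOL_BLOCKS = {
    1: ((0.0, 120.0),),
    2: ((0.0, 60.0), (180.0, 240.0)),
    3: ((0.0, 24.0), (48.0, 72.0), (96.0, 120.0), (144.0, 168.0), (192.0, 216.0)),
}


def make_protocol_schedule(protocol: int, dose: float) -> DrugSchedule:
    """Treatment protocols 1-3 over a 240 h horizon.

    Protocol 1: one 120 h session (0-120 h).  Protocol 2: two sessions,
    0-60 h and 180-240 h.  Protocol 3: five 24 h sessions starting at 0,
    48, 96, 144 and 192 h.  Each protocol totals 120 h on drug and 120 h off.
    """
    if protocol not in _PROTOCOL_BLOCKS:
        raise ValueError(f"unknown protocol {protocol}; choose 1, 2 or 3")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    blocks = _PROTOCOL_BLOCKS[protocol]
    return DrugSchedule(
        intervals=tuple((a, b, dose) for a, b in blocks), horizon=240.0
    )


# ---------------------------------------------------------------------------
# growth delay


@dataclass(frozen=True)
class GrowthDelayResult:
    """Growth delay in hours; ``flagged`` marks a treated curve that never
    regrew above its nadir (the delay is then the horizon, a lower bound)."""

    delay_h: float
    flagged: bool = False

    def __float__(self) -> float:
        return self.delay_h


def growth_delay(
    treated: Trajectory,
    control: Trajectory,
    method: str = "shift",
    regrow_factor: float = 2.0,
    threshold: float | None = None,
) -> GrowthDelayResult:
    """Time shift of the treated regrowth curve relative to the control.

    ``method='shift'`` (default): grid-search the lag tau (multiples of the
    recording cadence) minimizing the mean squared log-mismatch between the
    treated total N(t) and the control total N(t - tau), restricted to the
    post-nadir regrowth phase (times after the treated total first exceeds
    ``regrow_factor`` times its nadir).  ``method='threshold'``: difference
    of the first crossing times of ``threshold`` (default: 4x the common
    initial total).
    """
    t = np.asarray(treated.times, dtype=float)
    if len(t) != len(control.times) or not np.allclose(t, control.times):
        raise ValueError("treated and control trajectories must share times")
    n_t = treated.total()
    n_c = control.total()
    if not np.isclose(n_t[0], n_c[0], rtol=1e-6):
        raise ValueError("treated and control must share the initial total")

    if method == "threshold":
        thr = threshold if threshold is not None else 4.0 * n_t[0]
        cross_t = _first_crossing(t, n_t, thr)
        cross_c = _first_crossing(t, n_c, thr)
        if cross_t is None:
            return GrowthDelayResult(delay_h=float(t[-1]), flagged=True)
        if cross_c is None:
            raise ValueError("control never crosses the threshold")
        return GrowthDelayResult(delay_h=float(cross_t - cross_c))
    if method != "shift":
        raise ValueError(f"unknown growth-delay method: {method!r}")

    i_nadir = int(np.argmin(n_t))
    if i_nadir == 0:
        i_start = 0  # no transient decline: the whole curve is regrowth
    else:
        nadir = n_t[i_nadir]
        regrown = np.nonzero(
            (np.arange(len(t)) >= i_nadir) & (n_t >= regrow_factor * nadir)
        )[0]
        if len(regrown) == 0:
            return GrowthDelayResult(delay_h=float(t[-1]), flagged=True)
        i_start = int(regrown[0])

    log_t = np.log(np.maximum(n_t, 1e-300))
    log_c = np.log(np.maximum(n_c, 1e-300))
    window = np.arange(i_start, len(t))
    min_overlap = max(2, len(window) // 4)
    best_tau, best_mse = 0.0, np.inf
    for lag in range(0, len(t)):
        idx = window[window - lag >= 0]
        if len(idx) < min_overlap:
            break
        mse = float(np.mean((log_t[idx] - log_c[idx - lag]) ** 2))
        if mse < best_mse - 1e-15:
            best_mse, best_tau = mse, float(t[lag] - t[0])
    return GrowthDelayResult(delay_h=best_tau)


def response_amplitude(traj: Trajectory) -> float:
    """Largest cell-number change of a treated trajectory (cells).

    Measured as the maximum drawdown of the total cell number: the largest
    decrease from a running maximum to any later point.  Captures the
    amplitude of the up-and-down swings a treatment schedule imprints on
    the growth curve (a monotone curve has amplitude 0).
    """
    tot = traj.total()
    run_max = np.maximum.accumulate(tot)
    return float(np.max(run_max - tot))


def _first_crossing(t: np.ndarray, n: np.ndarray, thr: float) -> float | None:
    above = np.nonzero(n >= thr)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(t[0])
    # linear interpolation between the bracketing samples
    f = (thr - n[i - 1]) / (n[i] - n[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))
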