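"""Biological process terms of the kinetic transport model.

The state of each constitutive class i is a density u_i(x, t) over the
normalized P-gp activity x.  Its evolution combines

* conservative phenotype drift with velocity ``v_i = v_T + v_I``:
  microvesicle (MV)-mediated transfer, driven by the extracellular MV pool
  M(t), and drug-gated Lamarckian induction;
* a nonlocal birth term with kernel ``W_i(x, x')``: parents at activity x'
  divide at rate ``r_i(x')`` and place daughters around
  ``x' + lambda_rev * (b_i - x')`` (division-driven reversion to basal);
* logistic-type crowding decay ``g_i`` and the therapy function
  ``T(x, C)`` (Darwinian selection: low-P-gp cells are killed preferentially);
* the MV pool ODE with shedding by resistant donors and uptake by
  sensitive acceptors.

By default the resistant class neither takes up MVs nor responds to
induction; it only sheds (its basal P-gp level is constitutive).  All
functions are vectorized over x.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as _sla
from scipy import stats as _sst

from .grid import ActivityGrid, quadrature_weights
from .params import ProcessParameters
from .state import SystemState

__all__ = [
    "hill_factor",
    "protection_factor",
    "therapy_rate",
    "induction_velocity",
    "transfer_velocity",
    "transfer_amplitude",
    "proliferation_rate",
    "proliferation_kernel",
    "birth_operator",
    "crowding_decay",
    "mean_proliferation_rate",
    "mv_flux",
    "basal_gaussian_density",
    "equilibrium_density",
    "equilibrium_growth_rate",
]


# ---------------------------------------------------------------------------
# therapy function (Darwinian selection)


def hill_factor(C: float, p: ProcessParameters) -> float:
    """Hill dose-response factor ``C^h / (C50^h + C^h)`` in [0, 1)."""
    if C < 0:
        raise ValueError(f"drug concentration must be >= 0, got {C}")
    if C == 0.0:
        return 0.0
    ch = C**p.h_drug
    return float(ch / (p.C50**p.h_drug + ch))


def protection_factor(x, p: ProcessParameters):
    """P-gp protection sigmoid ``1 / (1 + exp((x - x_half) / w_prot))``.

    Decreasing in x: high-activity cells efflux the drug and escape killing.
    """
    z = (np.asarray(x, dtype=float) - p.x_half) / p.w_prot
    return 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))


def therapy_rate(x, C: float, p: ProcessParameters):
    """Drug kill rate T(x, C) (1/h): Hill in dose, protective sigmoid in x."""
    return p.delta_max * hill_factor(C, p) * protection_factor(x, p)


# ---------------------------------------------------------------------------
# phenotype drift velocities (conservative part)


def induction_velocity(x, C: float, p: ProcessParameters, grid: ActivityGrid):
    """Lamarckian induction velocity v_I (activity/h).

    Drug-gated drift toward higher P-gp; the boundary factor
    ``(x_max - x)/(x_max - x_min)`` vanishes at the upper boundary so no
    advective flux leaves the domain.
    """
    x = np.asarray(x, dtype=float)
    return p.alpha_I * hill_factor(C, p) * (grid.x_max - x) / grid.span


def transfer_amplitude(C: float, p: ProcessParameters) -> float:
    """MV-transfer amplitude kappa(C): kappaD at/above the drug threshold, else kappa0."""
    return p.kappaD if C >= p.drug_transfer_threshold else p.kappa0


def transfer_velocity(x, M: float, C: float, p: ProcessParameters, grid: ActivityGrid):
    """MV-mediated transfer velocity v_T = kappa(C) * M * (x_max - x)/span.

    Proportional to the extracellular MV concentration M; the amplitude
    switches ten-fold (with calibrated defaults) when the drug is present.
    """
    if M < 0:
        raise ValueError(f"M must be >= 0, got {M}")
    x = np.asarray(x, dtype=float)
    return transfer_amplitude(C, p) * M * (grid.x_max - x) / grid.span


# ---------------------------------------------------------------------------
# proliferation kernel and crowding (non-conservative part)


def proliferation_rate(x, index: int, p: ProcessParameters, grid: ActivityGrid):
    """Division rate r_i(x) (1/h), nonincreasing in x via the efflux cost."""
    r_max = {1: p.r_max_1, 2: p.r_max_2}[index]
    x = np.asarray(x, dtype=float)
    return r_max * np.maximum(0.0, 1.0 - p.c_cost * (x - grid.x_min) / grid.span)


def _kernel_columns(
    grid: ActivityGrid, index: int, p: ProcessParameters, rule: str
) -> np.ndarray:
    """Daughter-placement densities phi_i(x | x'), one column per parent cell.

    Truncated Gaussians centered at ``x' + lambda_rev * (b_i - x')`` with
    scale sigma_div, renormalized so each column integrates to exactly 1
    under the grid quadrature (truncate-and-renormalize boundary handling).
    """
    b = {1: p.b1, 2: p.b2}[index]
    c = grid.centers
    w = quadrature_weights(grid, rule)
    means = c + p.lambda_rev * (b - c)  # shape (n,), one per parent
    z = (c[:, None] - means[None, :]) / p.sigma_div
    phi = np.exp(-0.5 * z**2)
    norm = w @ phi  # integral of each column
    return phi / norm[None, :]


_BIRTH_CACHE: dict[tuple, np.ndarray] = {}


def birth_operator(
    grid: ActivityGrid, index: int, p: ProcessParameters, rule: str = "midpoint"
) -> np.ndarray:
    """Discrete birth operator A with ``(A @ u)(x) = int W_i(x, x') u(x') dx'``.

    ``A[i, j] = r_i(x'_j) * phi_i(x_i | x'_j) * w_j``; cached per (grid,
    class, kernel-relevant parameters).
    """
    b = {1: p.b1, 2: p.b2}[index]
    r_max = {1: p.r_max_1, 2: p.r_max_2}[index]
    key = (grid, index, rule, b, r_max, p.c_cost, p.lambda_rev, p.sigma_div)
    A = _BIRTH_CACHE.get(key)
    if A is None:
        w = quadrature_weights(grid, rule)
        r = proliferation_rate(grid.centers, index, p, grid)
        A = _kernel_columns(grid, index, p, rule) * (r * w)[None, :]
        if len(_BIRTH_CACHE) > 64:
            _BIRTH_CACHE.clear()
        _BIRTH_CACHE[key] = A
    return A


def proliferation_kernel(
    x,
    x_parent: float,
    index: int,
    p: ProcessParameters,
    grid: ActivityGrid,
    rule: str = "midpoint",
):
    """Kernel W_i(x, x') = r_i(x') * phi_i(x | x') for a single parent activity.

    The daughter density phi is normalized on the grid quadrature, so
    ``int W_i(x, x') dx = r_i(x')`` holds exactly on the grid.
    """
    if not (grid.contains(x_parent) and np.all(grid.contains(x))):
        raise ValueError("activities must lie within the grid range")
    b = {1: p.b1, 2: p.b2}[index]
    mean = x_parent + p.lambda_rev * (b - x_parent)
    w = quadrature_weights(grid, rule)
    col = np.exp(-0.5 * ((grid.centers - mean) / p.sigma_div) ** 2)
    norm = float(w @ col)
    x = np.asarray(x, dtype=float)
    phi = np.exp(-0.5 * ((x - mean) / p.sigma_div) ** 2) / norm
    return float(proliferation_rate(x_parent, index, p, grid)) * phi


def mean_proliferation_rate(state: SystemState, p: ProcessParameters) -> float:
    """Population-mean division rate r-bar (1/h); 0 for an empty state."""
    w = quadrature_weights(state.grid)
    c = state.grid.centers
    n1 = w @ state.u1.values
    n2 = w @ state.u2.values
    n_tot = n1 + n2
    if n_tot <= 0:
        return 0.0
    num = w @ (proliferation_rate(c, 1, p, state.grid) * state.u1.values) + w @ (
        proliferation_rate(c, 2, p, state.grid) * state.u2.values
    )
    return float(num / n_tot)


def crowding_decay(state: SystemState, p: ProcessParameters) -> tuple[float, float]:
    """Crowding decay rates (g1, g2) = (N_tot / K_cap) * r-bar for both classes.

    Logistic-type saturation: the per-capita net growth r-bar - g vanishes
    when the total population reaches the carrying capacity.
    """
    w = quadrature_weights(state.grid)
    n_tot = float(w @ state.u1.values + w @ state.u2.values)
    g = (n_tot / p.K_cap) * mean_proliferation_rate(state, p)
    return g, g


def mv_flux(state: SystemState, p: ProcessParameters) -> float:
    """Right-hand side of the MV pool ODE dM/dt (MV units/h).

    Gamma_1 = -gamma_up * M (uptake by sensitive acceptors),
    Gamma_2 = +gamma_shed * (x - x_min)/span (shedding grows with donor
    P-gp level), plus optional first-order clearance.
    """
    grid = state.grid
    w = quadrature_weights(grid)
    uptake = p.gamma_up * state.M * float(w @ state.u1.values)
    shed = p.gamma_shed * float(w @ (grid.rel(grid.centers) * state.u2.values))
    return shed - uptake - p.mv_clearance * state.M


# ---------------------------------------------------------------------------
# basal profiles


def basal_gaussian_density(
    grid: ActivityGrid, index: int, p: ProcessParameters
) -> np.ndarray:
    """Truncated Gaussian seed profile N(b_i, s_basal) on [x_min, x_max].

    Normalized to unit mass under the grid quadrature.
    """
    b = {1: p.b1, 2: p.b2}[index]
    a_, b_ = (grid.x_min - b) / p.s_basal, (grid.x_max - b) / p.s_basal
    pdf = _sst.truncnorm.pdf(grid.centers, a_, b_, loc=b, scale=p.s_basal)
    w = quadrature_weights(grid)
    return pdf / float(w @ pdf)


_EQ_CACHE: dict[tuple, np.ndarray] = {}


def equilibrium_density(
    grid: ActivityGrid, index: int, p: ProcessParameters
) -> np.ndarray:
    """Drug-free stationary (basal) activity profile of one class.

    With zero velocities and an x-independent death rate, the normalized
    density relaxes to the Perron eigenvector of the birth operator; this
    profile *is* the operational basal distribution of the class (the
    truncated Gaussian only seeds the kernel's reversion target).  Unit
    mass under the grid quadrature; cached.
    """
    b = {1: p.b1, 2: p.b2}[index]
    r_max = {1: p.r_max_1, 2: p.r_max_2}[index]
    key = (grid, index, b, r_max, p.c_cost, p.lambda_rev, p.sigma_div)
    u = _EQ_CACHE.get(key)
    if u is None:
        A = birth_operator(grid, index, p)
        vals, vecs = _sla.eig(A)
        k = int(np.argmax(vals.real))
        u = np.abs(vecs[:, k].real)
        w = quadrature_weights(grid)
        u = u / float(w @ u)
        if len(_EQ_CACHE) > 64:
            _EQ_CACHE.clear()
        _EQ_CACHE[key] = u
    return u.copy()


def equilibrium_growth_rate(
    grid: ActivityGrid, index: int, p: ProcessParameters
) -> float:
    """Asymptotic drug-free per-capita growth rate of one class (1/h)."""
    A = birth_operator(grid, index, p)
    vals = _sla.eigvals(A)
    return float(np.max(vals.real))
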