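"""System state: the pair of activity densities and the microvesicle pool."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ActivityGrid, quadrature_weights

__all__ = ["SubpopulationDensity", "SystemState", "total_cells"]


@dataclass
class SubpopulationDensity:
    """Activity density of one constitutive class.

    ``values`` holds cells per unit activity on the grid cells; ``index`` is
    the constitutive class (1 = sensitive / low basal P-gp, 2 = resistant /
    high basal P-gp).
    """

    values: np.ndarray
    index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.index not in (1, 2):
            raise ValueError(f"index must be 1 or 2, got {self.index}")
        if self.values.ndim != 1:
            raise ValueError("density values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("density values must be >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    def total(self, grid: ActivityGrid, rule: str = "midpoint") -> float:
        return float(quadrature_weights(grid, rule) @ self.values)


@dataclass
class SystemState:
    """Densities u1, u2 on a shared grid, MV concentration M, and time t (h)."""

    grid: ActivityGrid
    u1: SubpopulationDensity
    u2: SubpopulationDensity
    M: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        if len(self.u1.values) != n or len(self.u2.values) != n:
            raise ValueError("both densities must live on the state's grid")
        if self.u1.index != 1 or self.u2.index != 2:
            raise ValueError("u1 must have index 1 and u2 index 2")
        if self.M < 0:
            raise ValueError(f"M must be >= 0, got {self.M}")

    @classmethod
    def from_arrays(
        cls,
        grid: ActivityGrid,
        u1: np.ndarray,
        u2: np.ndarray,
        M: float = 0.0,
        t: float = 0.0,
    ) -> "SystemState":
        return cls(
            grid=grid,
            u1=SubpopulationDensity(values=u1, index=1),
            u2=SubpopulationDensity(values=u2, index=2),
            M=M,
            t=t,
        )

    def copy(self) -> "SystemState":
        return SystemState.from_arrays(
            self.grid, self.u1.values.copy(), self.u2.values.copy(), self.M, self.t
        )

    def mixture_density(self) -> np.ndarray:
        return self.u1.values + self.u2.values


def total_cells(state: SystemState, rule: str = "midpoint") -> np.ndarray:
    """Cell number per class, ``[N1, N2]``, by quadrature over the grid."""
    w = quadrature_weights(state.grid, rule)
    return np.array([w @ state.u1.values, w @ state.u2.values])
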