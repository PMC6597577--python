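"""Discretization of the P-gp activity axis.

The structuring variable ``x`` is a normalized log-fluorescence P-gp
activity living on ``[x_min, x_max]`` (default ``[0, 1]``).  Densities are
represented by their cell averages on a uniform finite-volume grid, so the
natural quadrature weight is ``dx`` per cell (exact for constants over the
full domain).  A composite trapezoid rule on the cell centers is available
for callers that treat the values as point samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ActivityGrid", "quadrature_weights"]


@dataclass(frozen=True)
class ActivityGrid:
    """Uniform grid on the activity interval ``[x_min, x_max]``.

    Parameters
    ----------
    x_min, x_max : float
        Bounds of the normalized P-gp activity axis; ``x_min < x_max``.
    n_bins : int
        Number of finite-volume cells, at least 8.
    """

    x_min: float = 0.0
    x_max: float = 1.0
    n_bins: int = 200

    def __post_init__(self) -> None:
        if not np.isfinite(self.x_min) or not np.isfinite(self.x_max):
            raise ValueError("grid bounds must be finite")
        if not self.x_min < self.x_max:
            raise ValueError(f"x_min must be < x_max, got [{self.x_min}, {self.x_max}]")
        if self.n_bins < 8:
            raise ValueError(f"n_bins must be >= 8, got {self.n_bins}")

    @property
    def span(self) -> float:
        return self.x_max - self.x_min

    @property
    def dx(self) -> float:
        return self.span / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        """Cell edges, shape ``(n_bins + 1,)``, strictly increasing."""
        return np.linspace(self.x_min, self.x_max, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        """Cell midpoints, shape ``(n_bins,)``."""
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def rel(self, x: np.ndarray | float) -> np.ndarray | float:
        """Map activity to the unit interval: ``(x - x_min) / (x_max - x_min)``."""
        return (np.asarray(x) - self.x_min) / self.span

    def contains(self, x: np.ndarray | float) -> np.ndarray | bool:
        x = np.asarray(x)
        return (x >= self.x_min) & (x <= self.x_max)


def quadrature_weights(grid: ActivityGrid, rule: str = "midpoint") -> np.ndarray:
    """Quadrature weights over the cell centers.

    ``midpoint`` (finite-volume) weights every cell by ``dx`` and is exact
    for cell-averaged data; ``trapezoid`` and ``simpson`` apply the composite
    rules to the center nodes (their support is ``[centers[0], centers[-1]]``,
    i.e. the domain minus half a cell at each end).
    """
    n, dx = grid.n_bins, grid.dx
    if rule == "midpoint":
        return np.full(n, dx)
    if rule == "trapezoid":
        w = np.full(n, dx)
        w[0] = w[-1] = 0.5 * dx
        return w
    if rule == "simpson":
        if n % 2 == 0:
            # composite Simpson needs an odd node count; fall back to trapezoid
            w = np.full(n, dx)
            w[0] = w[-1] = 0.5 * dx
            return w
        w = np.ones(n)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        return w * dx / 3.0
    raise ValueError(f"unknown quadrature rule: {rule!r}")
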