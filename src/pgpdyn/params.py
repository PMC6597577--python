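"""Process parameters of the resistance-kinetics model.

Every rate constant and shape parameter of the biological process terms
(transfer and induction velocities, proliferation kernel, crowding decay,
therapy function and microvesicle fluxes) lives in a single immutable
:class:`ProcessParameters` record.  A calibrated default set ships with the
package (``data/default_params.yaml``) and is the referent of the worked
examples and the acceptance computations.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ProcessParameters", "default_params", "load_params", "save_params"]


@dataclass(frozen=True)
class ProcessParameters:
    """Rate constants and shape parameters of the kinetic transport model.

    Units: activities are dimensionless (normalized log-P-gp on the grid
    interval), times in hours, drug concentrations in nM, microvesicle (MV)
    concentrations in arbitrary units, cell counts in cells.

    Attributes
    ----------
    b1, b2 : float
        Basal activity centers of the sensitive (1) and resistant (2)
        classes; ``b1 < b2``.
    s_basal : float
        Width of the basal (seed) activity distribution.
    r_max_1, r_max_2 : float
        Maximal proliferation rates (1/h) per class, attained at ``x_min``.
    c_cost : float
        Proliferation cost slope versus activity (dimensionless): cells
        paying the efflux-pump cost divide more slowly.
    K_cap : float
        Carrying capacity (cells) of the culture well.
    lambda_rev : float
        Per-division reversion fraction toward the basal center, in (0, 1].
    sigma_div : float
        Daughter-activity dispersion of the division kernel.
    alpha_I : float
        Induction velocity amplitude (activity/h at saturating drug).
    C50 : float
        Drug concentration of half-maximal effect (nM).
    h_drug : float
        Hill exponent of the dose response.
    delta_max : float
        Maximal drug kill rate (1/h).
    x_half, w_prot : float
        Midpoint and width of the P-gp protection sigmoid in the therapy
        function: high-activity cells efflux the drug and escape killing.
    kappa0, kappaD : float
        MV-transfer velocity amplitudes without / with drug
        (activity/h per MV unit).
    gamma_shed : float
        MV shedding rate per resistant (donor) cell (MV units/cell/h).
    gamma_up : float
        MV uptake rate per sensitive (acceptor) cell (1/cell/h).
    drug_transfer_threshold : float
        Drug concentration (nM) at or above which ``kappaD`` applies.
    mv_clearance : float
        Optional first-order MV clearance rate (1/h); default 0 (off).
    """

    b1: float = 0.25
    b2: float = 0.70
    s_basal: float = 0.07
    r_max_1: float = 0.035
    r_max_2: float = 0.030
    c_cost: float = 0.3
    K_cap: float = 2.0e6
    lambda_rev: float = 0.95
    sigma_div: float = 0.07
    alpha_I: float = 0.03
    C50: float = 40.0
    h_drug: float = 2.0
    delta_max: float = 0.12
    x_half: float = 0.45
    w_prot: float = 0.06
    kappa0: float = 2.0e-4
    kappaD: float = 2.0e-3
    gamma_shed: float = 5.0e-6
    gamma_up: float = 1.0e-6
    drug_transfer_threshold: float = 1.0
    mv_clearance: float = 0.0

    def __post_init__(self) -> None:
        rates = {
            "s_basal": self.s_basal,
            "r_max_1": self.r_max_1,
            "r_max_2": self.r_max_2,
            "c_cost": self.c_cost,
            "K_cap": self.K_cap,
            "sigma_div": self.sigma_div,
            "alpha_I": self.alpha_I,
            "C50": self.C50,
            "h_drug": self.h_drug,
            "delta_max": self.delta_max,
            "w_prot": self.w_prot,
            "kappa0": self.kappa0,
            "kappaD": self.kappaD,
            "gamma_shed": self.gamma_shed,
            "gamma_up": self.gamma_up,
            "drug_transfer_threshold": self.drug_transfer_threshold,
            "mv_clearance": self.mv_clearance,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0.0 < self.lambda_rev <= 1.0:
            raise ValueError(f"lambda_rev must be in (0, 1], got {self.lambda_rev}")
        if not self.b1 < self.b2:
            raise ValueError(f"b1 must be < b2, got b1={self.b1}, b2={self.b2}")
        if self.sigma_div <= 0:
            raise ValueError("sigma_div must be > 0")
        if self.K_cap <= 0:
            raise ValueError("K_cap must be > 0")

    def replace(self, **changes: float) -> "ProcessParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def checksum(self) -> str:
        """Stable sha256 of the parameter values (used in output headers)."""
        payload = ",".join(
            f"{k}={v!r}" for k, v in sorted(self.to_dict().items())
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_params(path: str | Path) -> ProcessParameters:
    """Read parameters from a flat ``key: value`` YAML file.

    Unknown keys are rejected; missing keys fall back to the packaged
    calibrated defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must contain a flat mapping")
    known = {f.name for f in dataclasses.fields(ProcessParameters)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return ProcessParameters(**{k: float(v) for k, v in raw.items()})


def save_params(p: ProcessParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=True)


_DEFAULT: ProcessParameters | None = None


def default_params() -> ProcessParameters:
    """The packaged calibrated-default parameter set."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("pgpdyn.data").joinpath("default_params.yaml")
        raw = yaml.safe_load(ref.read_text())
        _DEFAULT = ProcessParameters(**{k: float(v) for k, v in raw.items()})
    return _DEFAULT
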