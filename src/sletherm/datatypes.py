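"""Domain types for temperature-dependent solubility modeling.

All temperatures are absolute (kelvin) and all solubilities are solute mole
fractions at saturation. Celsius inputs are deliberately rejected rather
than converted: a temperature below 200 K in this problem domain is almost
certainly a Celsius value that slipped through, and silent conversion is
the classic thermodynamics bug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .constants import GAS_CONSTANT
from .exceptions import ValidationError

__all__ = [
    "SolubilityPoint",
    "SolubilityDataset",
    "FusionProperties",
    "DissolutionThermo",
    "ApelblatParams",
    "BinaryParams",
    "FitResult",
    "SlePrediction",
]


@dataclass(frozen=True)
class SolubilityPoint:
    """A single saturation measurement: mole fraction ``x_exp`` at ``temperature`` (K)."""

    temperature: float
    x_exp: float
    x_uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.temperature > 0.0) or not math.isfinite(self.temperature):
            raise ValidationError(
                f"temperature must be a positive kelvin value, got {self.temperature!r}"
            )
        if not (0.0 < self.x_exp < 1.0):
            raise ValidationError(
                f"mole fraction must lie in (0, 1), got {self.x_exp!r}"
            )
        if self.x_uncertainty is not None and not (self.x_uncertainty >= 0.0):
            raise ValidationError(
                f"x_uncertainty must be non-negative, got {self.x_uncertainty!r}"
            )


@dataclass
class SolubilityDataset:
    """Ordered temperature–solubility series for one solute in one solvent.

    Points are sorted by temperature on construction; duplicate temperatures
    are rejected because every model here treats x as a function of T.
    """

    solute_name: str
    solvent_name: str
    points: Sequence[SolubilityPoint]
    pressure_note: str = "0.1 MPa"

    def __post_init__(self) -> None:
        pts = sorted(self.points, key=lambda p: p.temperature)
        temps = [p.temperature for p in pts]
        for t1, t2 in zip(temps, temps[1:]):
            if t1 == t2:
                raise ValidationError(
                    f"duplicate temperature {t1} K in dataset "
                    f"{self.solute_name!r}/{self.solvent_name!r}"
                )
        self.points = list(pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p.temperature for p in self.points], dtype=float)

    @property
    def mole_fractions(self) -> np.ndarray:
        return np.array([p.x_exp for p in self.points], dtype=float)

    @property
    def uncertainties(self) -> np.ndarray:
        return np.array(
            [math.nan if p.x_uncertainty is None else p.x_uncertainty for p in self.points],
            dtype=float,
        )

    def require_min_points(self, n: int, context: str = "fit") -> None:
        if len(self.points) < n:
            raise ValidationError(
                f"{context} requires at least {n} points; dataset "
                f"{self.solvent_name!r} has {len(self.points)}"
            )


@dataclass(frozen=True)
class FusionProperties:
    """Melting temperature, molar enthalpy of fusion and the derived entropy.

    ``ds_fus`` may be omitted, in which case it is computed as
    ``dh_fus / t_melt``; a supplied value inconsistent with that identity is
    rejected.
    """

    t_melt: float
    dh_fus: float
    ds_fus: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.t_melt > 0.0):
            raise ValidationError(f"t_melt must be positive, got {self.t_melt!r}")
        if not (self.dh_fus > 0.0):
            raise ValidationError(f"dh_fus must be positive, got {self.dh_fus!r}")
        derived = self.dh_fus / self.t_melt
        if self.ds_fus is None:
            object.__setattr__(self, "ds_fus", derived)
        elif abs(self.ds_fus - derived) > 1e-9 * abs(derived):
            raise ValidationError(
                f"ds_fus={self.ds_fus!r} inconsistent with dh_fus/t_melt={derived!r}"
            )


@dataclass(frozen=True)
class DissolutionThermo:
    """Apparent dissolution thermodynamics at the mean harmonic temperature.

    The three functions are tied by ``ds_sol = (dh_sol - dg_sol) / t_hm``;
    construction enforces that identity to 1e-9 relative.
    """

    dh_sol: float
    dg_sol: float
    ds_sol: float
    t_hm: float
    r_squared: float = math.nan

    def __post_init__(self) -> None:
        if not (self.t_hm > 0.0):
            raise ValidationError(f"t_hm must be positive, got {self.t_hm!r}")
        implied = (self.dh_sol - self.dg_sol) / self.t_hm
        scale = max(abs(implied), abs(self.ds_sol), 1e-30)
        if abs(self.ds_sol - implied) > 1e-9 * scale:
            raise ValidationError(
                f"ds_sol={self.ds_sol!r} violates (dh_sol - dg_sol)/t_hm={implied!r}"
            )


@dataclass(frozen=True)
class ApelblatParams:
    """Parameters of the modified Apelblat correlation ln x = a + b/T + c ln T."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"Apelblat parameter {name} must be finite")


#: Allowed non-randomness range for the NRTL sigma parameter.
NRTL_SIGMA_RANGE = (0.2, 0.47)


@dataclass(frozen=True)
class BinaryParams:
    """Binary interaction parameters for the Wilson or NRTL model.

    Wilson: Lambda_ij = exp(a_ij + b_ij / T).
    NRTL:   tau_ij = a_ij + b_ij / T, G_ij = exp(-sigma * tau_ij).

    Component 1 is the solute, component 2 the solvent, everywhere.
    """

    model_tag: Literal["wilson", "nrtl"]
    a12: float
    b12: float
    a21: float
    b21: float
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.model_tag not in ("wilson", "nrtl"):
            raise ValidationError(f"model_tag must be 'wilson' or 'nrtl', got {self.model_tag!r}")
        for name in ("a12", "b12", "a21", "b21"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"binary parameter {name} must be finite")
        if self.model_tag == "nrtl":
            lo, hi = NRTL_SIGMA_RANGE
            if not (lo <= self.sigma <= hi):
                raise ValidationError(
                    f"NRTL sigma must lie in [{lo}, {hi}], got {self.sigma!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.a12, self.b12, self.a21, self.b21], dtype=float)

    def with_values(self, a12: float, b12: float, a21: float, b21: float) -> "BinaryParams":
        return replace(self, a12=a12, b12=b12, a21=a21, b21=b21)


@dataclass
class FitResult:
    """Outcome of a correlation fit: parameters, goodness-of-fit, diagnostics.

    ``residuals`` are per-point relative deviations (x_calc - x_exp)/x_exp,
    and ``ard_percent`` their mean absolute value times 100.
    """

    params: Union[ApelblatParams, BinaryParams]
    ard_percent: float
    residuals: np.ndarray
    converged: bool
    objective_value: float
    message: str = ""

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.converged and not (self.ard_percent >= 0.0):
            raise ValidationError(f"ard_percent must be non-negative, got {self.ard_percent!r}")


@dataclass(frozen=True)
class SlePrediction:
    """Solution of the solid–liquid equilibrium condition at one temperature."""

    temperature: float
    x_calc: float
    gamma: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.converged:
            if not (0.0 < self.x_calc < 1.0):
                raise ValidationError(
                    f"converged SLE solution must have x in (0,1), got {self.x_calc!r}"
                )
            if not (self.gamma > 0.0):
                raise ValidationError(f"gamma must be positive, got {self.gamma!r}")
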