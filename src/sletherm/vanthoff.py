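"""Modified van't Hoff analysis of apparent dissolution thermodynamics.

The temperature dependence of saturation mole fraction is summarised by an
ordinary least-squares line of ln x against u = (1/T - 1/T_hm), where T_hm
is the mean harmonic temperature of the measurement grid. The slope and
intercept give the *apparent* (activity-uncorrected) dissolution enthalpy
and Gibbs energy,

    dH_sol = -R * slope,     dG_sol = -R * T_hm * intercept,

and the entropy follows from the identity dS_sol = (dH_sol - dG_sol)/T_hm.
Centring on 1/T_hm decorrelates slope and intercept, so shifting T_hm moves
dG_sol and dS_sol but leaves dH_sol untouched.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import GAS_CONSTANT
from .datatypes import DissolutionThermo, FusionProperties, SolubilityDataset
from .exceptions import ValidationError

__all__ = [
    "harmonic_mean_temperature",
    "fusion_entropy",
    "VantHoffModel",
    "vant_hoff_fit",
]


def harmonic_mean_temperature(temperatures: Iterable[float]) -> float:
    """Mean harmonic temperature n / sum(1/T_i) of a temperature grid (K)."""
    temps = np.asarray(list(temperatures), dtype=float)
    if temps.size == 0:
        raise ValidationError("temperature list must be non-empty")
    if np.any(temps <= 0) or not np.all(np.isfinite(temps)):
        raise ValidationError("all temperatures must be positive and finite")
    return temps.size / float(np.sum(1.0 / temps))


def fusion_entropy(t_melt: float, dh_fus: float) -> FusionProperties:
    """Derive the molar entropy of fusion dS_fus = dH_fus / T_m.

    Parameters are the melting temperature (K) and molar enthalpy of fusion
    (J/mol); the returned record carries all three fusion properties.
    """
    return FusionProperties(t_melt=t_melt, dh_fus=dh_fus)


def _as_temperature_array(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValidationError("temperatures must be a 1-D array or a single column")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("all temperatures must be positive and finite")
    return arr


class VantHoffModel(RegressorMixin, BaseEstimator):
    """Apparent dissolution thermodynamics by modified van't Hoff regression.

    Scikit-learn style regressor: ``fit(T, x)`` takes temperatures (K) and
    saturation mole fractions, ``predict(T)`` returns mole fractions from
    the fitted line.

    Parameters
    ----------
    t_hm : float, optional
        Mean harmonic temperature (K) at which the apparent thermodynamic
        functions are evaluated. When None, computed from the training
        temperatures. A multi-solvent study sharing one temperature grid
        should pass the grid's common value so every solvent is referenced
        to the same T_hm.

    Attributes
    ----------
    t_hm_, slope_, intercept_ : regression frame and line coefficients
    dh_sol_, dg_sol_, ds_sol_ : apparent enthalpy (J/mol), Gibbs energy
        (J/mol) and entropy (J/mol/K) of dissolution
    r_squared_ : squared Pearson correlation of the regression
    thermo_ : DissolutionThermo record bundling the above
    """

    def __init__(self, t_hm: Optional[float] = None):
        self.t_hm = t_hm

    def fit(self, X, y):
        temps = _as_temperature_array(X)
        x = np.asarray(y, dtype=float)
        if x.shape != temps.shape:
            raise ValidationError("temperature and mole-fraction arrays must align")
        if temps.size < 3:
            raise ValidationError("van't Hoff regression requires at least 3 points")
        if np.any(x <= 0) or np.any(x >= 1):
            raise ValidationError("mole fractions must lie in (0, 1)")
        if np.ptp(temps) == 0.0:
            raise ValidationError("degenerate design: zero variance in temperature")

        t_hm = harmonic_mean_temperature(temps) if self.t_hm is None else float(self.t_hm)
        if t_hm <= 0:
            raise ValidationError("t_hm must be positive")
        u = 1.0 / temps - 1.0 / t_hm
        fit = stats.linregress(u, np.log(x))

        self.t_hm_ = t_hm
        self.slope_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.r_squared_ = float(fit.rvalue) ** 2
        self.dh_sol_ = -GAS_CONSTANT * self.slope_
        self.dg_sol_ = -GAS_CONSTANT * t_hm * self.intercept_
        self.ds_sol_ = (self.dh_sol_ - self.dg_sol_) / t_hm
        self.thermo_ = DissolutionThermo(
            dh_sol=self.dh_sol_,
            dg_sol=self.dg_sol_,
            ds_sol=self.ds_sol_,
            t_hm=t_hm,
            r_squared=self.r_squared_,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        temps = _as_temperature_array(X)
        u = 1.0 / temps - 1.0 / self.t_hm_
        return np.exp(self.intercept_ + self.slope_ * u)


def vant_hoff_fit(dataset: SolubilityDataset, t_hm: Optional[float] = None) -> DissolutionThermo:
    """Fit the modified van't Hoff line to one dataset and return its thermodynamics."""
    dataset.require_min_points(3, "van't Hoff regression")
    model = VantHoffModel(t_hm=t_hm)
    model.fit(dataset.temperatures, dataset.mole_fractions)
    return model.thermo_
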