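"""Modified Apelblat correlation ln x = A + B/T + C ln T.

The three-parameter form descends from the Clausius–Clapeyron relation with
a linearly temperature-dependent enthalpy; C = 0 recovers the plain
two-parameter van't Hoff line in 1/T.

Because the model is linear in (A, B, C) once solubilities are taken in log
space, fitting starts from an exact linear least-squares solve and then
polishes under the requested objective. The default objective stays in log
space; ``objective="relative"`` minimises squared relative deviations in x
instead, which weights the points essentially identically for deviations of
a few percent.
"""

from __future__ import annotations

import warnings
from typing import Literal, Union

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import ApelblatParams, FitResult, SolubilityDataset
from .exceptions import ValidationError
from .metrics import ard_percent

__all__ = ["apelblat_evaluate", "apelblat_fit", "ApelblatModel"]

Objective = Literal["log", "relative"]


def apelblat_evaluate(params: ApelblatParams, temperature) -> Union[float, np.ndarray]:
    """Evaluate x = exp(A + B/T + C ln T) at one or many temperatures (K).

    A result at or above x = 1 is physically meaningless for a solubility
    and triggers a UserWarning; the value is returned uncapped so callers
    can see how far outside the domain the parameters sit.
    """
    temps = np.asarray(temperature, dtype=float)
    if np.any(temps <= 0) or not np.all(np.isfinite(temps)):
        raise ValidationError("temperature must be positive and finite")
    ln_x = params.a + params.b / temps + params.c * np.log(temps)
    if np.any(ln_x >= 0):
        warnings.warn(
            "Apelblat evaluation gives x >= 1 (ln x >= 0); parameters are "
            "outside the physically meaningful range at this temperature",
            UserWarning,
            stacklevel=2,
        )
    x = np.exp(ln_x)
    return float(x) if np.isscalar(temperature) else x


class ApelblatModel(RegressorMixin, BaseEstimator):
    """Modified Apelblat solubility correlation as a scikit-learn regressor.

    Parameters
    ----------
    objective : {'log', 'relative'}
        Loss polished after the linear warm start: squared residuals in
        ln x, or squared relative deviations in x.

    Attributes
    ----------
    params_ : ApelblatParams
    ard_percent_ : average relative deviation (%) on the training data
    result_ : FitResult with residuals and convergence diagnostics
    """

    def __init__(self, objective: Objective = "log"):
        self.objective = objective

    def fit(self, X, y):
        if self.objective not in ("log", "relative"):
            raise ValidationError(f"unknown objective {self.objective!r}")
        temps = np.asarray(X, dtype=float)
        if temps.ndim == 2 and temps.shape[1] == 1:
            temps = temps[:, 0]
        x = np.asarray(y, dtype=float)
        if temps.shape != x.shape or temps.ndim != 1:
            raise ValidationError("temperature and mole-fraction arrays must align")
        if temps.size < 4:
            raise ValidationError("Apelblat fit requires at least 4 points (3 parameters)")
        if np.any(temps <= 0) or np.any(x <= 0) or np.any(x >= 1):
            raise ValidationError("require T > 0 and x in (0, 1)")

        design = np.column_stack([np.ones_like(temps), 1.0 / temps, np.log(temps)])
        ln_x = np.log(x)
        warm, *_ = np.linalg.lstsq(design, ln_x, rcond=None)

        if self.objective == "log":
            def residual(p):
                return design @ p - ln_x
        else:
            def residual(p):
                return (np.exp(design @ p) - x) / x

        sol = least_squares(residual, warm, method="lm", max_nfev=2000)
        x_calc = np.exp(design @ sol.x)
        rel = (x_calc - x) / x

        self.params_ = ApelblatParams(a=float(sol.x[0]), b=float(sol.x[1]), c=float(sol.x[2]))
        self.ard_percent_ = ard_percent(x_calc, x)
        self.result_ = FitResult(
            params=self.params_,
            ard_percent=self.ard_percent_,
            residuals=rel,
            converged=bool(sol.success),
            objective_value=float(sol.cost),
            message=sol.message,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        temps = np.asarray(X, dtype=float)
        if temps.ndim == 2 and temps.shape[1] == 1:
            temps = temps[:, 0]
        return np.asarray(apelblat_evaluate(self.params_, temps), dtype=float)


def apelblat_fit(dataset: SolubilityDataset, objective: Objective = "log") -> FitResult:
    """Fit the modified Apelblat correlation to one dataset."""
    dataset.require_min_points(4, "Apelblat fit")
    model = ApelblatModel(objective=objective)
    model.fit(dataset.temperatures, dataset.mole_fractions)
    return model.result_
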