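"""Synthetic solubility datasets with known ground truth.

Emulates the experimental regime of the built-in study: seven temperatures
on a 288.2–318.2 K grid, mole fractions around 1e-5 to 1e-2, and
multiplicative log-normal measurement noise,

    x_i = x_model(T_i) * exp(eps_i),   eps_i ~ Normal(0, noise_cv),

matching the roughly constant ~2% *relative* uncertainty of saturation
measurements (additive noise would misrepresent the small-x solvents).
The generating model may be any of the package's four families; the ground
truth is returned alongside the dataset so recovery studies need no
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple, Union

import numpy as np

from .activity import sle_solve
from .apelblat import apelblat_evaluate
from .constants import GAS_CONSTANT
from .datatypes import (
    ApelblatParams,
    BinaryParams,
    DissolutionThermo,
    FusionProperties,
    SolubilityDataset,
    SolubilityPoint,
)
from .exceptions import GenerationError, ValidationError

__all__ = ["GeneratorSpec", "generate", "DEFAULT_TEMPERATURES"]

#: Temperature grid of the emulated study (K).
DEFAULT_TEMPERATURES: Tuple[float, ...] = (288.2, 293.2, 298.2, 303.2, 308.2, 313.2, 318.2)

ModelTag = Literal["vanthoff", "apelblat", "wilson", "nrtl"]
TrueParams = Union[DissolutionThermo, ApelblatParams, BinaryParams]


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic dataset.

    ``true_params`` must match ``model_tag``: a DissolutionThermo for
    'vanthoff' (the line is rebuilt from dh_sol, dg_sol and t_hm), an
    ApelblatParams for 'apelblat', a BinaryParams for 'wilson'/'nrtl'
    (which also require ``fusion``). ``noise_cv`` is the standard deviation
    of the log-normal noise; 0 gives exact model values.
    """

    model_tag: ModelTag
    true_params: TrueParams
    fusion: Optional[FusionProperties] = None
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES
    noise_cv: float = 0.02
    seed: int = 0
    solvent_name: str = "synthetic solvent"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv must be non-negative, got {self.noise_cv!r}")
        expected = {
            "vanthoff": DissolutionThermo,
            "apelblat": ApelblatParams,
            "wilson": BinaryParams,
            "nrtl": BinaryParams,
        }
        if self.model_tag not in expected:
            raise ValidationError(f"unknown model_tag {self.model_tag!r}")
        if not isinstance(self.true_params, expected[self.model_tag]):
            raise ValidationError(
                f"true_params for {self.model_tag!r} must be "
                f"{expected[self.model_tag].__name__}"
            )
        if self.model_tag in ("wilson", "nrtl"):
            if self.fusion is None:
                raise ValidationError("activity-model generation requires fusion properties")
            if any(t >= self.fusion.t_melt for t in self.temperatures):
                raise ValidationError("all temperatures must lie below the melting point")
            if self.true_params.model_tag != self.model_tag:
                raise ValidationError(
                    f"true_params.model_tag {self.true_params.model_tag!r} "
                    f"does not match {self.model_tag!r}"
                )
        if len(self.temperatures) == 0:
            raise ValidationError("temperature grid must be non-empty")


def _model_values(spec: GeneratorSpec) -> np.ndarray:
    temps = np.asarray(spec.temperatures, dtype=float)
    if spec.model_tag == "vanthoff":
        p = spec.true_params
        slope = -p.dh_sol / GAS_CONSTANT
        intercept = -p.dg_sol / (GAS_CONSTANT * p.t_hm)
        return np.exp(intercept + slope * (1.0 / temps - 1.0 / p.t_hm))
    if spec.model_tag == "apelblat":
        return np.asarray(apelblat_evaluate(spec.true_params, temps), dtype=float)
    out = np.empty_like(temps)
    for i, t in enumerate(temps):
        pred = sle_solve(spec.true_params, spec.fusion, float(t))
        if not pred.converged:
            raise GenerationError(
                f"SLE solve did not converge at T = {t} K for the generating parameters"
            )
        out[i] = pred.x_calc
    return out


def generate(spec: GeneratorSpec) -> Tuple[SolubilityDataset, dict]:
    """Draw one synthetic dataset; returns (dataset, ground_truth sidecar).

    The sidecar records the generating model, parameters, noise level, seed
    and the noise-free model curve, and is JSON-friendly apart from the
    parameter record itself.
    """
    x_model = _model_values(spec)
    bad = ~((x_model > 0.0) & (x_model < 1.0) & np.isfinite(x_model))
    if np.any(bad):
        t_bad = np.asarray(spec.temperatures, dtype=float)[bad][0]
        raise GenerationError(
            f"model evaluates outside (0, 1) at T = {t_bad} K (x = {x_model[bad][0]!r})"
        )
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_cv, size=x_model.size) if spec.noise_cv > 0 else np.zeros(x_model.size)
    x_obs = x_model * np.exp(eps)
    if np.any(x_obs >= 1.0):
        t_bad = np.asarray(spec.temperatures, dtype=float)[x_obs >= 1.0][0]
        raise GenerationError(f"noisy draw reached x >= 1 at T = {t_bad} K")

    dataset = SolubilityDataset(
        solute_name="synthetic solute",
        solvent_name=spec.solvent_name,
        points=[
            SolubilityPoint(float(t), float(xv))
            for t, xv in zip(spec.temperatures, x_obs)
        ],
    )
    truth = {
        "model_tag": spec.model_tag,
        "true_params": spec.true_params,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
        "temperatures": [float(t) for t in spec.temperatures],
        "x_model": [float(v) for v in x_model],
    }
    return dataset, truth
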