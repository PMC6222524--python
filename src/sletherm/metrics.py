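"""Goodness-of-fit metrics for solubility correlations."""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError

__all__ = ["ard_percent"]


def ard_percent(x_calc, x_exp) -> float:
    """Average relative deviation in percent: (100/N) * sum |x_calc - x_exp| / x_exp."""
    calc = np.asarray(x_calc, dtype=float)
    exp_ = np.asarray(x_exp, dtype=float)
    if calc.shape != exp_.shape:
        raise ValidationError(
            f"length mismatch: x_calc has shape {calc.shape}, x_exp {exp_.shape}"
        )
    if calc.size == 0:
        raise ValidationError("ARD%% undefined for empty inputs")
    if np.any(exp_ <= 0):
        raise ValidationError("all experimental mole fractions must be positive")
    return float(100.0 * np.mean(np.abs(calc - exp_) / exp_))
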