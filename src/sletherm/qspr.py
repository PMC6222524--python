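"""Descriptor–solubility correlation across solvents.

A minimal QSPR step: the Pearson correlation between ln x at a common
reference temperature and one named physical descriptor of each solvent
(pKa, dielectric constant, Hansen parameters, ...). Descriptor values are
user-supplied — the package ships only the schema, not a descriptor
database. When a dataset lacks a point at the reference temperature, ln x
is interpolated linearly in 1/T, consistent with the near-linear behaviour
of ln x in reciprocal temperature.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SolubilityDataset
from .exceptions import FormatError, LookupDataError, ValidationError

__all__ = ["SolventDescriptorTable", "correlate_descriptor"]

#: Default comparison temperature (K) for cross-solvent correlations.
DEFAULT_REFERENCE_TEMPERATURE = 298.2


class SolventDescriptorTable:
    """Named physical descriptors per solvent.

    Backed by a nested mapping ``{solvent: {descriptor: value}}``; loadable
    from a long-format CSV with header ``solvent,descriptor,value``.
    """

    def __init__(self, values: Mapping[str, Mapping[str, float]] = ()):
        self._values: Dict[str, Dict[str, float]] = {}
        for solvent, descriptors in dict(values).items():
            for name, value in dict(descriptors).items():
                self.set(solvent, name, value)

    def set(self, solvent: str, descriptor: str, value: float) -> None:
        value = float(value)
        if not np.isfinite(value):
            raise ValidationError(
                f"descriptor {descriptor!r} for {solvent!r} must be finite"
            )
        self._values.setdefault(solvent, {})[descriptor] = value

    def get(self, solvent: str, descriptor: str) -> float:
        try:
            return self._values[solvent][descriptor]
        except KeyError:
            raise LookupDataError(
                f"no descriptor {descriptor!r} for solvent {solvent!r}"
            ) from None

    def solvents(self) -> Sequence[str]:
        return list(self._values)

    @classmethod
    def from_csv(cls, source: Union[str, Path, TextIO]) -> "SolventDescriptorTable":
        try:
            frame = pd.read_csv(source)
        except Exception as exc:
            raise FormatError(f"could not parse descriptor CSV: {exc}") from exc
        missing = [c for c in ("solvent", "descriptor", "value") if c not in frame.columns]
        if missing:
            raise FormatError(f"descriptor CSV missing column(s) {missing}")
        table = cls()
        for row in frame.itertuples():
            table.set(str(row.solvent), str(row.descriptor), float(row.value))
        return table


def _ln_x_at(dataset: SolubilityDataset, temperature: float) -> float:
    """ln x at the requested temperature, interpolating linearly in 1/T if needed."""
    temps = dataset.temperatures
    ln_x = np.log(dataset.mole_fractions)
    exact = np.nonzero(np.isclose(temps, temperature, rtol=0, atol=1e-9))[0]
    if exact.size:
        return float(ln_x[exact[0]])
    if not (temps.min() <= temperature <= temps.max()):
        raise ValidationError(
            f"reference temperature {temperature} K outside the measured range "
            f"[{temps.min()}, {temps.max()}] for {dataset.solvent_name!r}"
        )
    # np.interp needs ascending abscissae; 1/T reverses the ordering
    inv_t = 1.0 / temps[::-1]
    return float(np.interp(1.0 / temperature, inv_t, ln_x[::-1]))


def correlate_descriptor(
    datasets: Sequence[SolubilityDataset],
    descriptors: SolventDescriptorTable,
    descriptor_name: str,
    reference_temperature: float = DEFAULT_REFERENCE_TEMPERATURE,
) -> float:
    """Pearson correlation of ln x (at the reference temperature) with one descriptor.

    Computed across solvents: each dataset contributes one (ln x, descriptor)
    pair. Requires at least 3 solvents.
    """
    if len(datasets) < 3:
        raise ValidationError("descriptor correlation requires at least 3 solvents")
    ln_x = [_ln_x_at(ds, reference_temperature) for ds in datasets]
    desc = [descriptors.get(ds.solvent_name, descriptor_name) for ds in datasets]
    r, _ = stats.pearsonr(ln_x, desc)
    return float(r)
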