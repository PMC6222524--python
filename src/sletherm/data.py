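"""Built-in experimental dataset: metoprolol succinate in seven organic solvents.

Saturation mole fractions at seven temperatures between 288.2 and 318.2 K
under 0.1 MPa, with the reported absolute uncertainties, plus the DSC fusion
properties of the solute (melting point 410.15 K, enthalpy of fusion
121.3 kJ/mol). Values in the source table are printed as 10^3 * x; the
transcription below divides that factor out so mole fractions are stored at
natural scale.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .datatypes import FusionProperties, SolubilityDataset, SolubilityPoint
from .exceptions import LookupDataError

__all__ = ["builtin_dataset", "METOPROLOL_SUCCINATE_SOLVENTS"]

_TEMPERATURES_K = (288.2, 293.2, 298.2, 303.2, 308.2, 313.2, 318.2)

# (10^3 * x, 10^3 * u_x) per temperature, per solvent.
_TABLE: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "methanol": (
        (2.845, 0.068), (3.548, 0.096), (4.741, 0.107), (6.424, 0.228),
        (8.745, 0.091), (12.547, 0.012), (16.631, 0.112),
    ),
    "ethanol": (
        (0.435, 0.010), (0.559, 0.012), (0.822, 0.015), (1.047, 0.009),
        (1.416, 0.050), (2.175, 0.084), (3.172, 0.098),
    ),
    "n-butanol": (
        (0.177, 0.006), (0.259, 0.001), (0.377, 0.019), (0.536, 0.024),
        (0.788, 0.065), (1.111, 0.085), (1.567, 0.086),
    ),
    "n-propanol": (
        (0.165, 0.006), (0.258, 0.008), (0.373, 0.006), (0.548, 0.005),
        (0.831, 0.019), (1.240, 0.027), (1.795, 0.012),
    ),
    "isopropanol": (
        (0.074, 0.002), (0.109, 0.002), (0.160, 0.001), (0.219, 0.003),
        (0.316, 0.011), (0.465, 0.027), (0.659, 0.053),
    ),
    "ethyl acetate": (
        (0.019, 0.002), (0.028, 0.005), (0.040, 0.003), (0.058, 0.004),
        (0.084, 0.006), (0.118, 0.009), (0.165, 0.008),
    ),
    "acetone": (
        (0.061, 0.004), (0.089, 0.002), (0.130, 0.002), (0.173, 0.004),
        (0.234, 0.008), (0.299, 0.003), (0.425, 0.015),
    ),
}

#: Solvent order of the source table.
METOPROLOL_SUCCINATE_SOLVENTS: Tuple[str, ...] = tuple(_TABLE)

_FUSION = FusionProperties(t_melt=410.15, dh_fus=121300.0)


def builtin_dataset(name: str) -> Tuple[List[SolubilityDataset], FusionProperties]:
    """Return the named built-in study: per-solvent datasets plus fusion properties.

    Currently only ``"metoprolol_succinate"`` is available.
    """
    if name != "metoprolol_succinate":
        raise LookupDataError(
            f"unknown built-in dataset {name!r}; available: 'metoprolol_succinate'"
        )
    datasets = [
        SolubilityDataset(
            solute_name="metoprolol succinate",
            solvent_name=solvent,
            points=[
                SolubilityPoint(t, x_milli * 1e-3, u_milli * 1e-3)
                for t, (x_milli, u_milli) in zip(_TEMPERATURES_K, rows)
            ],
        )
        for solvent, rows in _TABLE.items()
    ]
    return datasets, _FUSION
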