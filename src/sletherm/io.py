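"""Readers and writers for solubility datasets.

Two formats are supported and nothing else:

* CSV with header ``solvent,temperature_K,x,u_x`` (``u_x`` optional per row);
* JSON as an array of dataset objects mirroring :class:`SolubilityDataset`.

Mole fractions are stored at natural scale (e.g. ``2.845e-3``), never the
"x * 10^3" convention common in printed tables.
"""

from __future__ import annotations

import io as _io
import json
import math
from pathlib import Path
from typing import List, Optional, Sequence, TextIO, Union

import pandas as pd

from .datatypes import SolubilityDataset, SolubilityPoint
from .exceptions import FormatError, ValidationError

__all__ = ["load_solubility_table", "write_solubility_table"]

Source = Union[str, Path, TextIO]

_CSV_COLUMNS = ("solvent", "temperature_K", "x")


def _infer_format(source: Source, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise FormatError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
        return fmt
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower()
        if suffix == ".json":
            return "json"
        if suffix == ".csv":
            return "csv"
    raise FormatError("format could not be inferred; pass format='csv' or 'json'")


def load_solubility_table(
    source: Source,
    format: Optional[str] = None,
    solute_name: str = "solute",
) -> List[SolubilityDataset]:
    """Load one dataset per distinct solvent from a CSV or JSON table.

    Parameters
    ----------
    source : path or open text stream
    format : {'csv', 'json'}, optional
        Inferred from the file suffix when omitted.
    solute_name : str
        Name recorded on CSV-loaded datasets (the CSV schema carries no solute column).

    Returns
    -------
    list of SolubilityDataset, one per solvent, points sorted by temperature.
    """
    fmt = _infer_format(source, format)
    if fmt == "csv":
        return _load_csv(source, solute_name)
    return _load_json(source)


def _load_csv(source: Source, solute_name: str) -> List[SolubilityDataset]:
    try:
        # round_trip parsing so write->load reproduces floats bit-for-bit
        frame = pd.read_csv(source, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"could not parse CSV solubility table: {exc}") from exc
    if frame.empty and frame.columns.size == 0:
        raise FormatError("empty file: no header row found")
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"CSV is missing required column(s) {missing}; "
            f"expected header solvent,temperature_K,x[,u_x]"
        )
    if frame.empty:
        raise FormatError("CSV contains a header but no data rows")

    datasets: List[SolubilityDataset] = []
    for solvent, group in frame.groupby("solvent", sort=False):
        points = []
        for row in group.itertuples():
            try:
                temperature = float(row.temperature_K)
                x = float(row.x)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"row {row.Index + 2}: non-numeric temperature_K or x"
                ) from exc
            u_x = getattr(row, "u_x", None)
            if u_x is not None and isinstance(u_x, float) and math.isnan(u_x):
                u_x = None
            try:
                points.append(
                    SolubilityPoint(temperature, x, None if u_x is None else float(u_x))
                )
            except ValidationError as exc:
                raise ValidationError(f"row {row.Index + 2}: {exc}") from exc
        datasets.append(SolubilityDataset(solute_name, str(solvent), points))
    return datasets


def _load_json(source: Source) -> List[SolubilityDataset]:
    try:
        if isinstance(source, (str, Path)):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.load(source)
    except json.JSONDecodeError as exc:
        raise FormatError(f"could not parse JSON solubility table: {exc}") from exc
    if not isinstance(payload, list):
        raise FormatError("JSON root must be an array of dataset objects")
    datasets = []
    for i, obj in enumerate(payload):
        try:
            points = [
                SolubilityPoint(
                    float(p["temperature"]),
                    float(p["x_exp"]),
                    None if p.get("x_uncertainty") is None else float(p["x_uncertainty"]),
                )
                for p in obj["points"]
            ]
            datasets.append(
                SolubilityDataset(
                    solute_name=obj["solute_name"],
                    solvent_name=obj["solvent_name"],
                    points=points,
                    pressure_note=obj.get("pressure_note", "0.1 MPa"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise FormatError(f"dataset entry {i}: malformed object ({exc})") from exc
    return datasets


def write_solubility_table(
    datasets: Sequence[SolubilityDataset],
    target: Union[str, Path, TextIO],
    format: Optional[str] = None,
) -> None:
    """Write datasets to CSV or JSON, the exact inverse of :func:`load_solubility_table`.

    Floats are serialized with :func:`repr` precision so a round trip
    reproduces every field bit-for-bit.
    """
    fmt = _infer_format(target, format)
    if fmt == "csv":
        rows = []
        for ds in datasets:
            for p in ds.points:
                rows.append(
                    {
                        "solvent": ds.solvent_name,
                        "temperature_K": repr(p.temperature),
                        "x": repr(p.x_exp),
                        "u_x": "" if p.x_uncertainty is None else repr(p.x_uncertainty),
                    }
                )
        frame = pd.DataFrame(rows, columns=["solvent", "temperature_K", "x", "u_x"])
        frame.to_csv(target, index=False)
    else:
        payload = [
            {
                "solute_name": ds.solute_name,
                "solvent_name": ds.solvent_name,
                "pressure_note": ds.pressure_note,
                "points": [
                    {
                        "temperature": p.temperature,
                        "x_exp": p.x_exp,
                        "x_uncertainty": p.x_uncertainty,
                    }
                    for p in ds.points
                ],
            }
            for ds in datasets
        ]
        if isinstance(target, (str, Path)):
            Path(target).write_text(json.dumps(payload, indent=1))
        else:
            json.dump(payload, target, indent=1)
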