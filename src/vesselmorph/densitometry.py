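"""Protein-expression quantification from integrated optical density (IOD).

Two measurement kinds are supported:

- ``IHC``: immunohistochemistry fields; the expression intensity of a record
  is the mean of its field IODs (three fields per slice by default), and the
  per-animal value is the mean over its slice-level means.
- ``WB``: Western blot; relative expression is the IOD ratio of the target
  band to the beta-actin reference band.

This module performs no hypothesis testing; its per-animal summaries feed
:mod:`vesselmorph.group_stats` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensitometryRecord",
    "ihc_expression",
    "wb_relative_expression",
    "records_from_frame",
    "expression_table",
]

KINDS = ("IHC", "WB")


@dataclass(frozen=True)
class DensitometryRecord:
    """IOD measurements for one animal (WB) or one slice (IHC)."""

    protein: str
    group: str
    animal: int | str
    kind: str
    iod_values: tuple[float, ...]
    reference_iod: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        values = tuple(float(v) for v in self.iod_values)
        if not values:
            raise ValueError("record carries no IOD values")
        if any(v <= 0 for v in values):
            raise ValueError("IOD values must be positive")
        if self.kind == "WB":
            if len(values) != 1:
                raise ValueError("WB records carry a single band IOD")
            if self.reference_iod is None or self.reference_iod <= 0:
                raise ValueError("WB records need a positive reference IOD")
        object.__setattr__(self, "iod_values", values)


def ihc_expression(record: DensitometryRecord) -> float:
    """Mean field IOD of an IHC record (expression intensity)."""
    if record.kind != "IHC":
        raise ValueError("ihc_expression expects an IHC record")
    return float(np.mean(record.iod_values))


def wb_relative_expression(record: DensitometryRecord) -> float:
    """Target-band IOD divided by the beta-actin reference IOD."""
    if record.kind != "WB":
        raise ValueError("wb_relative_expression expects a WB record")
    return record.iod_values[0] / record.reference_iod


def records_from_frame(frame: pd.DataFrame) -> list[DensitometryRecord]:
    """Parse the densitometry CSV dialect into records.

    Expects columns ``protein, group, animal, kind, field_or_band, iod,
    reference_iod``.  IHC rows are grouped into one record per slice, where
    the slice id is the ``s<slice>f<field>`` prefix of ``field_or_band``.
    """
    required = {"protein", "group", "animal", "kind", "field_or_band", "iod"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"densitometry table is missing columns {sorted(missing)}")
    records: list[DensitometryRecord] = []
    wb = frame[frame["kind"] == "WB"]
    for row in wb.itertuples(index=False):
        records.append(
            DensitometryRecord(
                protein=row.protein,
                group=row.group,
                animal=row.animal,
                kind="WB",
                iod_values=(row.iod,),
                reference_iod=float(row.reference_iod),
            )
        )
    ihc = frame[frame["kind"] == "IHC"].copy()
    if not ihc.empty:
        ihc["slice_key"] = ihc["field_or_band"].astype(str).str.split("f").str[0]
        for (protein, group, animal, _), sub in ihc.groupby(
            ["protein", "group", "animal", "slice_key"], sort=False, observed=True
        ):
            records.append(
                DensitometryRecord(
                    protein=protein,
                    group=group,
                    animal=animal,
                    kind="IHC",
                    iod_values=tuple(sub["iod"]),
                )
            )
    return records


def expression_table(records: Sequence[DensitometryRecord]) -> pd.DataFrame:
    """Per-animal expression values, long format.

    WB: relative expression per record.  IHC: mean over the animal's
    slice-level mean IODs.  Columns: ``protein, group, animal, kind, value``.
    """
    rows = []
    for rec in records:
        value = wb_relative_expression(rec) if rec.kind == "WB" else ihc_expression(rec)
        rows.append(
            {
                "protein": rec.protein,
                "group": rec.group,
                "animal": rec.animal,
                "kind": rec.kind,
                "value": value,
            }
        )
    columns = ["protein", "group", "animal", "kind", "value"]
    frame = pd.DataFrame(rows, columns=columns)
    return (
        frame.groupby(["protein", "group", "animal", "kind"], sort=False, observed=True)[
            "value"
        ]
        .mean()
        .reset_index()
    )
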