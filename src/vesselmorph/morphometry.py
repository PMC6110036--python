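"""Vessel cross-section morphometry.

From the inner areas of the outer elastic membrane (EEL), inner elastic
membrane (IEL) and the lumen, six indices are derived per slice:

- ``MA`` media area  = a_eel - a_iel
- ``IA`` intimal area = a_iel - a_lumen
- ``MT`` media thickness = sqrt(a_eel/pi) - sqrt(a_iel/pi)
- ``IT`` intimal thickness, two modes:
    * ``printed`` (default): sqrt(a_eel/pi) - sqrt(a_lumen/pi)
    * ``anatomical``: sqrt(a_iel/pi) - sqrt(a_lumen/pi)
- ``HRIA`` = IA / (IA + MA)
- ``HRIT`` = IT / (IT + MT)

Thicknesses are differences of equivalent-circle radii ``sqrt(A/pi)``; this
is the only reading of the source formulas with length units.  The
``printed`` IT mode keeps the outer membrane as reference for fidelity to the
published formula; ``anatomical`` uses the IEL, the anatomically intimal
bound.  Ratios are fractions internally; multiply by 100 for percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "RINGS",
    "MorphometryRecord",
    "polygon_area",
    "equivalent_radius",
    "compute_indices",
    "areas_from_contours",
    "indices_from_areas",
    "summarize",
    "INDEX_COLUMNS",
]

RINGS = ("EEL", "IEL", "LUMEN")
INDEX_COLUMNS = ("MA", "IA", "MT", "IT", "HRIA", "HRIT")

Mode = Literal["printed", "anatomical"]


@dataclass(frozen=True)
class MorphometryRecord:
    """Area triple plus the six derived indices for one slice (um / um^2)."""

    a_eel: float
    a_iel: float
    a_lumen: float
    MA: float
    IA: float
    MT: float
    IT: float
    HRIA: float
    HRIT: float


def polygon_area(vertices: np.ndarray) -> float:
    """Absolute shoelace area of a simple polygon.

    Invariant to cyclic rotation of the vertex list, orientation reversal and
    rigid motion.  The polygon may be explicitly closed (first vertex
    repeated) or implicitly closed.

    Raises
    ------
    ValueError
        Fewer than 3 distinct vertices, or self-intersecting boundary.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("vertices must be an (n, 2) array")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("a polygon needs at least 3 distinct vertices")
    if not Polygon(pts).is_valid:
        raise ValueError("polygon boundary is self-intersecting")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def equivalent_radius(area: float) -> float:
    """Radius of the circle with the given area."""
    if area < 0:
        raise ValueError("area must be nonnegative")
    return sqrt(area / pi)


def _safe_ratio(num: float, denom: float) -> float:
    # Degenerate denominator (e.g. normal vessel with no intima) -> ratio 0.
    return num / denom if denom > 0 else 0.0


def compute_indices(
    a_eel: float,
    a_iel: float,
    a_lumen: float,
    mode: Mode = "printed",
    label: str | None = None,
) -> MorphometryRecord:
    """Derive the six indices from one slice's area triple.

    Parameters
    ----------
    a_eel, a_iel, a_lumen : inner areas (um^2); must satisfy
        ``a_eel >= a_iel >= a_lumen >= 0``.
    mode : IT reference membrane, ``"printed"`` (outer) or ``"anatomical"``
        (inner).
    label : optional slice identifier used in error messages.
    """
    if mode not in ("printed", "anatomical"):
        raise ValueError(f"unknown mode {mode!r}")
    where = f" (slice {label})" if label is not None else ""
    if a_lumen < 0:
        raise ValueError(f"negative lumen area{where}")
    if not (a_eel >= a_iel >= a_lumen):
        raise ValueError(
            f"nesting violated{where}: expected a_eel >= a_iel >= a_lumen, "
            f"got {a_eel:.6g}, {a_iel:.6g}, {a_lumen:.6g}"
        )
    ma = a_eel - a_iel
    ia = a_iel - a_lumen
    r_eel = equivalent_radius(a_eel)
    r_iel = equivalent_radius(a_iel)
    r_lumen = equivalent_radius(a_lumen)
    mt = r_eel - r_iel
    it = (r_eel if mode == "printed" else r_iel) - r_lumen
    return MorphometryRecord(
        a_eel=a_eel,
        a_iel=a_iel,
        a_lumen=a_lumen,
        MA=ma,
        IA=ia,
        MT=mt,
        IT=it,
        HRIA=_safe_ratio(ia, ia + ma),
        HRIT=_safe_ratio(it, it + mt),
    )


def areas_from_contours(contours: pd.DataFrame, validate: bool = False) -> pd.DataFrame:
    """Shoelace areas per (group, animal, slice) from a long contour table.

    Expects columns ``group, animal, slice, ring, vertex_index, x_um, y_um``
    with ring in ``{EEL, IEL, LUMEN}``.  Returns one row per slice with
    columns ``a_eel_um2, a_iel_um2, a_lumen_um2``.

    With ``validate=True`` every ring is checked for simplicity via
    :func:`polygon_area`; the default path uses a vectorized shoelace sum.
    """
    required = {"group", "animal", "slice", "ring", "vertex_index", "x_um", "y_um"}
    missing = required - set(contours.columns)
    if missing:
        raise ValueError(f"contour table is missing columns {sorted(missing)}")
    df = contours.sort_values(["group", "animal", "slice", "ring", "vertex_index"])
    keys = ["group", "animal", "slice", "ring"]
    if validate:
        areas = df.groupby(keys, sort=False, observed=True).apply(
            lambda g: polygon_area(g[["x_um", "y_um"]].to_numpy()),
            include_groups=False,
        )
        out = areas.rename("area").reset_index()
    else:
        codes, starts = _segment_starts(df, keys)
        x = df["x_um"].to_numpy()
        y = df["y_um"].to_numpy()
        cross = x * _roll_segments(y, starts) - y * _roll_segments(x, starts)
        area = np.abs(np.add.reduceat(cross, starts)) / 2.0
        out = codes.assign(area=area)
    wide = out.pivot_table(
        index=["group", "animal", "slice"], columns="ring", values="area", sort=False
    ).reset_index()
    for ring in RINGS:
        if ring not in wide.columns:
            raise ValueError(f"contour table has no {ring} ring")
    return wide.rename(
        columns={"EEL": "a_eel_um2", "IEL": "a_iel_um2", "LUMEN": "a_lumen_um2"}
    )[["group", "animal", "slice", "a_eel_um2", "a_iel_um2", "a_lumen_um2"]]


def _segment_starts(df: pd.DataFrame, keys: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    ids = df.groupby(keys, sort=False, observed=True).ngroup().to_numpy()
    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    return df.iloc[starts][keys].reset_index(drop=True), starts


def _roll_segments(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    # roll each contiguous segment left by one (next vertex, wrapping)
    out = np.empty_like(values)
    out[:-1] = values[1:]
    ends = np.r_[starts[1:], len(values)] - 1
    out[ends] = values[starts]
    return out


def indices_from_areas(areas: pd.DataFrame, mode: Mode = "printed") -> pd.DataFrame:
    """Per-slice index table from an area table (see :func:`areas_from_contours`)."""
    rows = []
    for rec in areas.itertuples(index=False):
        label = f"{rec.group}/{rec.animal}/{rec.slice}"
        m = compute_indices(rec.a_eel_um2, rec.a_iel_um2, rec.a_lumen_um2, mode, label)
        rows.append(
            {
                "group": rec.group,
                "animal": rec.animal,
                "slice": rec.slice,
                "a_eel_um2": m.a_eel,
                "a_iel_um2": m.a_iel,
                "a_lumen_um2": m.a_lumen,
                **{k: getattr(m, k) for k in INDEX_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


def summarize(
    per_slice: pd.DataFrame, value_columns: tuple[str, ...] = INDEX_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate slice records to animal means, then group mean +/- SD.

    The animal value is the mean over its slices; the group value is the mean
    and sample SD (n-1 denominator) over animal values, with n the number of
    animals.  Returns ``(per_animal, per_group)``.
    """
    if per_slice.empty:
        raise ValueError("no records to summarize")
    cols = [c for c in value_columns if c in per_slice.columns]
    if not cols:
        raise ValueError("no value columns found to summarize")
    per_animal = (
        per_slice.groupby(["group", "animal"], sort=False, observed=True)[cols]
        .mean()
        .reset_index()
    )
    grouped = per_animal.groupby("group", sort=False, observed=True)
    mean = grouped[cols].mean()
    sd = grouped[cols].std(ddof=1)
    n = grouped.size().rename("n")
    per_group = mean.join(sd, lsuffix="_mean", rsuffix="_sd").join(n).reset_index()
    return per_animal, per_group
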