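"""Single-factor fuzzy comprehensive evaluation via TOPSIS closeness grades.

Treatment groups are scored on a groups x criteria matrix (e.g. hyperplasia
ratios HRIA and HRIT, both *cost* criteria: lower is better).  Each group's
Euclidean distances to the ideal (``d_plus``) and anti-ideal (``d_minus``)
criterion vectors yield the closeness grade ``C = d_minus / (d_plus +
d_minus)``; groups are then dense-ranked in descending ``C``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvalMatrix",
    "TopsisResult",
    "normalize",
    "ideal_points",
    "closeness",
    "dense_rank",
    "evaluate",
    "results_frame",
]

COST = "cost"
BENEFIT = "benefit"
_DIRECTIONS = (COST, BENEFIT)
_SCHEMES = ("vector", "minmax", "none")


@dataclass(frozen=True)
class EvalMatrix:
    """A groups x criteria decision matrix with directions and weights.

    Parameters
    ----------
    groups : ordered group labels (the judgement set).
    criteria : ordered criterion labels (the evaluation factor set).
    values : real matrix of shape ``(len(groups), len(criteria))``.
    directions : per-criterion ``"cost"`` (lower is better) or ``"benefit"``.
    weights : per-criterion nonnegative weights; normalized to sum to 1.
        Defaults to equal weights.
    """

    groups: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray
    directions: tuple[str, ...] = ()
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(str(g) for g in self.groups))
        object.__setattr__(self, "criteria", tuple(str(c) for c in self.criteria))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape != (len(self.groups), len(self.criteria)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.groups)} groups x {len(self.criteria)} criteria"
            )
        if len(self.groups) < 2:
            raise ValueError("at least 2 groups are required")
        if len(self.criteria) < 1:
            raise ValueError("at least 1 criterion is required")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain missing or non-finite entries")
        directions = tuple(self.directions) or (COST,) * len(self.criteria)
        for d in directions:
            if d not in _DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}; expected one of {_DIRECTIONS}")
        if len(directions) != len(self.criteria):
            raise ValueError("one direction per criterion is required")
        weights = np.asarray(self.weights or [1.0] * len(self.criteria), dtype=float)
        if weights.shape != (len(self.criteria),):
            raise ValueError("one weight per criterion is required")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        weights = weights / weights.sum()
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "weights", tuple(weights))

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        criteria: Sequence[str] | None = None,
        directions: Sequence[str] | None = None,
        weights: Sequence[float] | None = None,
    ) -> "EvalMatrix":
        """Build a matrix from a DataFrame indexed by group label."""
        cols = list(criteria) if criteria is not None else list(frame.columns)
        return cls(
            groups=tuple(frame.index.astype(str)),
            criteria=tuple(cols),
            values=frame[cols].to_numpy(dtype=float),
            directions=tuple(directions or ()),
            weights=tuple(weights or ()),
        )


@dataclass(frozen=True)
class TopsisResult:
    """Distances, closeness grade and dense rank for one group."""

    group: str
    d_plus: float
    d_minus: float
    closeness: float
    rank: int


def normalize(matrix: EvalMatrix, scheme: str = "vector") -> EvalMatrix:
    """Normalize each criterion column of the decision matrix.

    ``vector``
        Divide each column by its Euclidean norm (directions unchanged).
    ``minmax``
        Direction-aware affine map: the best-direction extreme becomes 1 and
        the worst 0, so all criteria become benefit-like.  Constant columns
        map to 0 with a warning.
    ``none``
        Pass-through.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    values = matrix.values
    if scheme == "none":
        return matrix
    if scheme == "vector":
        norms = np.linalg.norm(values, axis=0)
        if np.any(norms == 0):
            bad = [c for c, n in zip(matrix.criteria, norms) if n == 0]
            raise ValueError(f"zero-norm column(s) under vector scheme: {bad}")
        return replace(matrix, values=values / norms)
    # minmax
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    out = np.zeros_like(values)
    for j, direction in enumerate(matrix.directions):
        if span[j] == 0:
            warnings.warn(
                f"criterion {matrix.criteria[j]!r} is constant; min-max maps it to 0",
                stacklevel=2,
            )
            continue
        if direction == BENEFIT:
            out[:, j] = (values[:, j] - lo[j]) / span[j]
        else:
            out[:, j] = (hi[j] - values[:, j]) / span[j]
    return replace(matrix, values=out, directions=(BENEFIT,) * len(matrix.criteria))


def ideal_points(
    values: np.ndarray, directions: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-criterion best (ideal) and worst (anti-ideal) values across groups."""
    values = np.asarray(values, dtype=float)
    ideal = np.empty(values.shape[1])
    anti = np.empty(values.shape[1])
    for j, direction in enumerate(directions):
        if direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r}")
        col = values[:, j]
        if direction == COST:
            ideal[j], anti[j] = col.min(), col.max()
        else:
            ideal[j], anti[j] = col.max(), col.min()
    return ideal, anti


def closeness(d_plus: float, d_minus: float) -> float:
    """Closeness grade ``C = d_minus / (d_plus + d_minus)``, in [0, 1].

    Both distances zero is a degenerate single-point configuration; ``C`` is
    defined as 1 with a warning.
    """
    if d_plus < 0 or d_minus < 0:
        raise ValueError("distances must be nonnegative")
    total = d_plus + d_minus
    if total == 0:
        warnings.warn("both distances are 0 (degenerate); closeness defined as 1", stacklevel=2)
        return 1.0
    return d_minus / total


def dense_rank(values: Sequence[float]) -> np.ndarray:
    """Dense ranks in descending order: ties share a rank, ranks stay consecutive."""
    arr = np.asarray(values, dtype=float)
    distinct = np.unique(arr)[::-1]  # descending
    lookup = {v: i + 1 for i, v in enumerate(distinct)}
    return np.array([lookup[v] for v in arr], dtype=int)


def evaluate(matrix: EvalMatrix, scheme: str = "vector") -> list[TopsisResult]:
    """Full TOPSIS evaluation: normalize, weight, distance, closeness, rank.

    Returns one :class:`TopsisResult` per group, preserving input order.
    """
    norm = normalize(matrix, scheme)
    weighted = norm.values * np.asarray(norm.weights)
    ideal, anti = ideal_points(weighted, norm.directions)
    d_plus = np.linalg.norm(weighted - ideal, axis=1)
    d_minus = np.linalg.norm(weighted - anti, axis=1)
    c = np.array([closeness(p, m) for p, m in zip(d_plus, d_minus)])
    ranks = dense_rank(c)
    return [
        TopsisResult(group=g, d_plus=float(p), d_minus=float(m), closeness=float(ci), rank=int(r))
        for g, p, m, ci, r in zip(matrix.groups, d_plus, d_minus, c, ranks)
    ]


def results_frame(results: Sequence[TopsisResult]) -> pd.DataFrame:
    """Tabulate results; ``C`` carries full precision, ``C_3dp`` the 3-dp report."""
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "d_plus": [r.d_plus for r in results],
            "d_minus": [r.d_minus for r in results],
            "C": [r.closeness for r in results],
            "C_3dp": [round(r.closeness, 3) for r in results],
            "rank": [r.rank for r in results],
        }
    )
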