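"""Seeded synthetic cohorts: vessel contour geometry and densitometry tables.

The generator emulates the design of a rat balloon-injury study: treatment
groups with graded intimal hyperplasia, eight cross-section slices per
vessel, and protein-expression measurements (IHC field IODs, Western-blot
band IODs against a beta-actin reference).

Geometry model.  A slice is three nested closed polygons sampled on a common
angular grid: the outer elastic membrane (EEL) and inner elastic membrane
(IEL) are concentric about the section center; the lumen boundary is offset
by ``eccentricity x intima thickness`` to produce concentric or eccentric
stenosis.  Radii and thicknesses get multiplicative lognormal noise at the
configured coefficient of variation, both per section and per vertex;
nesting is enforced by clipping violating vertices back inside the enclosing
ring (reported via ``ContourSet.clipped``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "ContourSet",
    "DEFAULT_VERTEX_COUNT",
    "generate_section",
    "generate_cohort",
    "generate_densitometry",
    "default_groups",
    "default_cohort",
]

DEFAULT_VERTEX_COUNT = 128
_THICKNESS_FLOOR_UM = 1e-3


@dataclass(frozen=True)
class GroupSpec:
    """Generating parameters for one experimental group.

    ``intima_thickness_mean`` may be 0 (uninjured vessel, a single intimal
    cell layer without hyperplasia); all other length scales must be
    positive.  ``expression_effects`` maps protein label to the mean relative
    expression used by :func:`generate_densitometry`.
    """

    label: str
    n_animals: int
    lumen_radius_mean: float
    intima_thickness_mean: float
    media_thickness_mean: float
    eccentricity: float = 0.0
    cv: float = 0.1
    expression_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError(f"group {self.label!r}: n_animals must be >= 1")
        if self.lumen_radius_mean <= 0 or self.media_thickness_mean <= 0:
            raise ValueError(f"group {self.label!r}: radius/media means must be > 0")
        if self.intima_thickness_mean < 0:
            raise ValueError(f"group {self.label!r}: intima thickness must be >= 0")
        if not 0 <= self.eccentricity < 1:
            raise ValueError(f"group {self.label!r}: eccentricity must be in [0, 1)")
        if self.cv < 0:
            raise ValueError(f"group {self.label!r}: cv must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration: ordered groups plus sampling counts."""

    groups: tuple[GroupSpec, ...]
    slices_per_vessel: int = 8
    fields_per_slice: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels in cohort config")
        if self.slices_per_vessel < 1 or self.fields_per_slice < 1:
            raise ValueError("slices_per_vessel and fields_per_slice must be >= 1")

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


@dataclass(frozen=True)
class ContourSet:
    """Three nested closed polygons for one slice, vertices in um."""

    eel: np.ndarray
    iel: np.ndarray
    lumen: np.ndarray
    group: str = ""
    animal: int = 0
    slice: int = 0
    clipped: bool = False

    def rings(self) -> dict[str, np.ndarray]:
        return {"EEL": self.eel, "IEL": self.iel, "LUMEN": self.lumen}


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _radial_noise(
    rng: np.random.Generator, cv: float, theta: np.ndarray, harmonics: int = 8
) -> np.ndarray:
    """Smooth periodic multiplicative noise, pointwise lognormal at the given CV.

    A band-limited Gaussian field on the circle (random Fourier series up to
    ``harmonics``) is exponentiated, so each vertex radius factor is
    lognormal with mean 1 and coefficient of variation ``cv`` while adjacent
    vertices stay strongly correlated.  The bounded angular frequency keeps
    boundaries simple and makes the nesting clip in
    :func:`generate_section` reliable.
    """
    if cv == 0:
        return np.ones_like(theta)
    sigma2 = np.log1p(cv * cv)
    amp = np.sqrt(sigma2 / harmonics)
    k = np.arange(1, harmonics + 1)
    a = rng.normal(0.0, amp, size=harmonics)
    b = rng.normal(0.0, amp, size=harmonics)
    phase = np.outer(theta, k)
    g = np.cos(phase) @ a + np.sin(phase) @ b
    return np.exp(g - 0.5 * sigma2)


def _windowed_min(values: np.ndarray, half_window: int) -> np.ndarray:
    """Circular sliding minimum over ``2*half_window + 1`` samples."""
    if half_window <= 0:
        return values
    stacked = [np.roll(values, s) for s in range(-half_window, half_window + 1)]
    return np.min(stacked, axis=0)


def generate_section(
    spec: GroupSpec,
    rng: np.random.Generator,
    n_vertices: int = DEFAULT_VERTEX_COUNT,
) -> ContourSet:
    """Sample one vessel cross-section for the given group.

    Section-level draws of lumen radius and layer thicknesses and
    vertex-level radial jitter both use lognormal noise at ``spec.cv`` (never
    negative; a small positive floor guards thickness degeneracy).  The
    returned polygons are simple and nested: ``area(lumen) <= area(IEL) <=
    area(EEL)``.
    """
    cv = spec.cv
    r_lumen = max(spec.lumen_radius_mean * _lognormal_factors(rng, cv, ()), _THICKNESS_FLOOR_UM)
    t_intima = spec.intima_thickness_mean * _lognormal_factors(rng, cv, ())
    t_media = max(spec.media_thickness_mean * _lognormal_factors(rng, cv, ()), _THICKNESS_FLOOR_UM)

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])

    r_iel = (r_lumen + t_intima) * _radial_noise(rng, cv, theta)
    r_eel = (r_lumen + t_intima + t_media) * _radial_noise(rng, cv, theta)
    # keep the EEL strictly outside the IEL at every shared angle
    clipped = bool(np.any(r_iel > r_eel))
    r_iel = np.minimum(r_iel, r_eel)

    # lumen offset along a random direction by eccentricity x intima thickness
    phi = rng.uniform(0.0, 2.0 * np.pi)
    offset = spec.eccentricity * t_intima
    center = offset * np.array([np.cos(phi), np.sin(phi)])
    r_lum = (r_lumen * _radial_noise(rng, cv, theta)).copy()
    # Nesting bound: every IEL chord stays radially outside the minimum of
    # its endpoint radii, so capping each lumen vertex by a windowed minimum
    # of nearby IEL grid radii keeps the whole lumen polygon inside the IEL
    # (the window spans the grid cells a lumen edge can cross).  Clipping
    # moves a vertex along its ray from the lumen center, which shifts its
    # angle about the origin, so the constraint is re-checked iteratively.
    dtheta = 2.0 * np.pi / n_vertices
    c_sq = float(center @ center)
    c_dot_u = unit @ center
    for _ in range(30):
        pts = center + r_lum[:, None] * unit
        ang = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
        dist = np.hypot(pts[:, 0], pts[:, 1])
        if cv == 0 and offset == 0:
            # lumen vertices share the IEL grid angles exactly; chords coincide
            allowed = r_iel * (1.0 - 1e-7)
        else:
            gaps = np.diff(np.sort(ang))
            max_gap = max(gaps.max() if len(gaps) else 0.0, dtheta)
            half_window = min(int(np.ceil(max_gap / dtheta)) + 1, n_vertices // 4)
            r_iel_floor = _windowed_min(r_iel, half_window)
            # cos term: an IEL chord sags below its endpoint radii by up to
            # this factor where the perpendicular foot is interior
            allowed = (
                r_iel_floor[np.round(ang / dtheta).astype(int) % n_vertices]
                * np.cos(dtheta / 2.0)
                * (1.0 - 1e-7)
            )
        viol = dist > allowed
        if not np.any(viol):
            break
        clipped = True
        # pull each violating vertex back along its ray from the lumen
        # center until it sits on (or just inside) the permitted radius
        bound = allowed[viol]
        reach = -c_dot_u[viol] + np.sqrt(
            np.maximum(bound * bound - (c_sq - c_dot_u[viol] ** 2), 0.0)
        )
        new_r = np.minimum(reach, r_lum[viol])
        stuck = new_r >= r_lum[viol] * (1.0 - 1e-12)
        new_r[stuck] = r_lum[viol][stuck] * 0.9995
        r_lum[viol] = np.maximum(new_r, _THICKNESS_FLOOR_UM)
    pts = center + r_lum[:, None] * unit

    return ContourSet(
        eel=r_eel[:, None] * unit,
        iel=r_iel[:, None] * unit,
        lumen=pts,
        group=spec.label,
        clipped=clipped,
    )


def generate_cohort(
    config: CohortConfig, n_vertices: int = DEFAULT_VERTEX_COUNT
) -> tuple[pd.DataFrame, dict]:
    """Generate all sections of a cohort plus a truth sidecar.

    Returns a long contour table (columns ``group, animal, slice, ring,
    vertex_index, x_um, y_um``) with exactly ``n_animals x
    slices_per_vessel`` sections per group, and a JSON-serializable mapping
    group label -> generating parameters for recovery tests.  Deterministic
    for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    groups, animals, slices, rings, xs, ys = [], [], [], [], [], []
    ring_labels = np.repeat(["EEL", "IEL", "LUMEN"], n_vertices)
    vertex_index = np.tile(np.arange(n_vertices), 3)
    for spec in config.groups:
        for animal in range(1, spec.n_animals + 1):
            for slice_id in range(1, config.slices_per_vessel + 1):
                section = generate_section(spec, rng, n_vertices)
                xy = np.concatenate([section.eel, section.iel, section.lumen])
                groups.append(spec.label)
                animals.append(animal)
                slices.append(slice_id)
                xs.append(xy[:, 0])
                ys.append(xy[:, 1])
    n_sections = len(groups)
    contours = pd.DataFrame(
        {
            "group": np.repeat(groups, 3 * n_vertices),
            "animal": np.repeat(animals, 3 * n_vertices),
            "slice": np.repeat(slices, 3 * n_vertices),
            "ring": np.tile(ring_labels, n_sections),
            "vertex_index": np.tile(vertex_index, n_sections),
            "x_um": np.concatenate(xs),
            "y_um": np.concatenate(ys),
        }
    )
    truth = {
        spec.label: {
            **dataclasses.asdict(spec),
            "expression_effects": dict(spec.expression_effects),
        }
        for spec in config.groups
    }
    return contours, truth


def generate_densitometry(
    config: CohortConfig,
    proteins: Iterable[str] | None = None,
    base_iod: float = 100.0,
) -> pd.DataFrame:
    """Generate IHC field IODs and WB band IODs for every animal.

    Per animal and protein: one WB record whose target IOD is ``effect x
    reference IOD x lognormal noise`` (reference is the beta-actin band), and
    one IHC record per slice with ``fields_per_slice`` field IODs around the
    effect level.  Returns the densitometry CSV dialect: columns ``protein,
    group, animal, kind, field_or_band, iod, reference_iod``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    available = set().union(*(g.expression_effects.keys() for g in config.groups)) if config.groups else set()
    wanted = list(proteins) if proteins is not None else sorted(available)
    rows = []
    for spec in config.groups:
        for protein in wanted:
            if protein not in spec.expression_effects:
                raise KeyError(
                    f"unknown protein label {protein!r} for group {spec.label!r}"
                )
        for animal in range(1, spec.n_animals + 1):
            for protein in wanted:
                effect = spec.expression_effects[protein]
                reference = base_iod * _lognormal_factors(rng, spec.cv, ())
                target = effect * reference * _lognormal_factors(rng, spec.cv, ())
                rows.append(
                    {
                        "protein": protein,
                        "group": spec.label,
                        "animal": animal,
                        "kind": "WB",
                        "field_or_band": "band",
                        "iod": float(target),
                        "reference_iod": float(reference),
                    }
                )
                for slice_id in range(1, config.slices_per_vessel + 1):
                    level = base_iod * effect * _lognormal_factors(rng, spec.cv, ())
                    fields = level * _lognormal_factors(rng, spec.cv, config.fields_per_slice)
                    for f, iod in enumerate(fields, start=1):
                        rows.append(
                            {
                                "protein": protein,
                                "group": spec.label,
                                "animal": animal,
                                "kind": "IHC",
                                "field_or_band": f"s{slice_id}f{f}",
                                "iod": float(iod),
                                "reference_iod": np.nan,
                            }
                        )
    columns = ["protein", "group", "animal", "kind", "field_or_band", "iod", "reference_iod"]
    return pd.DataFrame(rows, columns=columns)


def default_groups(
    n_animals: int = 8, cv: float = 0.1, eccentricity: float = 0.3
) -> tuple[GroupSpec, ...]:
    """Default 10-group study design with graded intimal hyperplasia.

    Intima-thickness means are strictly ordered across the nine injured
    groups so that downstream efficacy ranking has a known ground truth;
    defaults put the hyperplasia ratio HRIA near 0.5 for the untreated model
    group and near 0.2 for the best treatment.  Expression effects scale a
    proliferation marker up and an inhibitor down with hyperplasia severity.
    """
    # label -> intima thickness (um); lumen radius 250 um, media 60 um
    intima = {
        "Normal": 0.0,
        "Astragalus-Angelica 1:1": 17.0,
        "Atorvastatin": 21.0,
        "Astragalus-Angelica 1:2": 27.0,
        "Astragalus-Angelica 1:5": 33.0,
        "Angelica": 40.0,
        "Astragalus-Angelica 5:1": 47.0,
        "Astragalus": 60.0,
        "Astragalus-Angelica 2:1": 66.0,
        "Model": 74.0,
    }
    order = [
        "Normal",
        "Model",
        "Astragalus",
        "Angelica",
        "Astragalus-Angelica 1:2",
        "Astragalus-Angelica 1:5",
        "Astragalus-Angelica 1:1",
        "Astragalus-Angelica 5:1",
        "Astragalus-Angelica 2:1",
        "Atorvastatin",
    ]
    groups = []
    for label in order:
        t = intima[label]
        severity = t / intima["Model"]
        groups.append(
            GroupSpec(
                label=label,
                n_animals=n_animals,
                lumen_radius_mean=250.0,
                intima_thickness_mean=t,
                media_thickness_mean=60.0,
                eccentricity=0.0 if t == 0 else eccentricity,
                cv=cv,
                expression_effects={
                    "PCNA": 1.0 + severity,
                    "TIMP-1": 2.0 - severity,
                },
            )
        )
    return tuple(groups)


def default_cohort(seed: int = 0, n_animals: int = 8, cv: float = 0.1) -> CohortConfig:
    """Default cohort configuration mirroring the study design."""
    return CohortConfig(groups=default_groups(n_animals=n_animals, cv=cv), seed=seed)
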