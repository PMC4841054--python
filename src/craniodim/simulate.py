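"""Synthetic 3D facial-landmark cohort generator.

Emulates the statistical structure the downstream analyses assume: a
bilaterally symmetric template face, an additive per-landmark sex
displacement field (+1/2 to males, -1/2 to females so the mid-sex average
stays on the template), per-age-group isotropic growth scaling, a height
model per (group, sex) cell, a height-coupled allometric shape field,
i.i.d. Gaussian landmark noise, and an arbitrary rigid device frame
(random proper rotation + translation) that superimposition must undo.

The generator makes no attempt to mimic a real cohort's landmark
covariance structure, asymmetry, or non-Gaussian digitizing error; it
provides ground truth (the injected displacement field and group scales)
against which estimator recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.stats import special_ortho_group

from .cohort import (
    AGE_GROUPS,
    AGE_GROUP_BY_LABEL,
    BILATERAL_PAIRS,
    DIRECT_MEASUREMENT_NAMES,
    LANDMARK_NAMES,
    MIDLINE_LANDMARKS,
    AgeGroup,
    Cohort,
    LandmarkConfiguration,
    SubjectRecord,
)

__all__ = [
    "FaceTemplate",
    "SimulationSpec",
    "make_template",
    "default_spec",
    "simulate_cohort",
    "spec_from_mapping",
]

_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}

# Idealized adult face, mm.  Axes: x lateral (midline plane x=0, right
# side x>0), y superior, z anterior.  Values chosen to give interlandmark
# distances in the normal adult range (e.g. nasal width ~34 mm,
# outercanthal width ~90 mm, morphological facial height ~105 mm).
_TEMPLATE_POINTS: dict[str, tuple[float, float, float]] = {
    "n": (0.0, 45.0, 5.0),
    "prn": (0.0, 15.0, 25.0),
    "sn": (0.0, 5.0, 12.0),
    "ls": (0.0, -8.0, 14.0),
    "sto": (0.0, -18.0, 10.0),
    "li": (0.0, -26.0, 12.0),
    "sl": (0.0, -36.0, 6.0),
    "gn": (0.0, -60.0, 4.0),
    "en_r": (16.0, 40.0, 0.0),
    "ex_r": (45.0, 38.0, -12.0),
    "al_r": (17.0, 10.0, 8.0),
    "sbal_r": (10.0, 5.0, 10.0),
    "cph_r": (5.0, -6.0, 13.0),
    "ch_r": (26.0, -18.0, 2.0),
    "ac_r": (16.0, 12.0, 4.0),
    "t_r": (70.0, 30.0, -70.0),
}

# Male-direction displacement field, mm at effect_scale=1, mirroring the
# dimorphic features the analyses should recover: nasion shifted inferiorly
# and anteriorly, pronasale more projecting, alare and tragion more lateral,
# endocanthion more posterior, sublabiale superior, chin more prominent,
# palpebral fissure more horizontal (exocanthion raised).
_SEX_EFFECT_POINTS: dict[str, tuple[float, float, float]] = {
    "n": (0.0, -1.0, 0.8),
    "prn": (0.0, -0.5, 1.5),
    "sn": (0.0, -0.2, 0.3),
    "ls": (0.0, 0.0, 0.2),
    "sto": (0.0, -0.1, 0.0),
    "li": (0.0, 0.3, -0.2),
    "sl": (0.0, 0.8, 0.3),
    "gn": (0.0, -0.5, 1.0),
    "en_r": (0.2, -0.3, -0.8),
    "ex_r": (0.3, 0.6, -0.4),
    "al_r": (1.0, -0.2, 0.2),
    "sbal_r": (0.5, -0.1, 0.1),
    "cph_r": (0.1, 0.0, 0.0),
    "ch_r": (0.3, -0.2, 0.0),
    "ac_r": (0.7, -0.1, 0.1),
    "t_r": (1.5, 0.5, 0.5),
}

# Growth-driven allometric shape field: mandible drops and nose projects as
# faces get bigger.  Unit-normalized at module import.
_ALLOMETRY_POINTS: dict[str, tuple[float, float, float]] = {
    "n": (0.0, 0.2, -0.2),
    "prn": (0.0, -0.3, 0.8),
    "sn": (0.0, -0.3, 0.2),
    "ls": (0.0, -0.2, 0.1),
    "sto": (0.0, -0.3, 0.0),
    "li": (0.0, -0.4, 0.1),
    "sl": (0.0, -0.6, 0.2),
    "gn": (0.0, -1.0, 0.5),
    "en_r": (0.1, 0.1, -0.1),
    "ex_r": (0.2, 0.1, -0.2),
    "al_r": (0.3, -0.2, 0.1),
    "sbal_r": (0.2, -0.1, 0.1),
    "cph_r": (0.1, -0.1, 0.0),
    "ch_r": (0.2, -0.3, 0.0),
    "ac_r": (0.2, -0.1, 0.0),
    "t_r": (0.4, 0.0, -0.2),
}


def _mirror_field(points: Mapping[str, tuple[float, float, float]], center: bool) -> np.ndarray:
    """Expand right-side + midline values to a full symmetric (24, 3) field."""
    arr = np.zeros((24, 3))
    for name, xyz in points.items():
        arr[_INDEX[name]] = xyz
    for right, left in BILATERAL_PAIRS:
        arr[_INDEX[left]] = arr[_INDEX[right]] * np.array([-1.0, 1.0, 1.0])
    for name in MIDLINE_LANDMARKS:
        arr[_INDEX[name], 0] = 0.0
    if center:
        arr = arr - arr.mean(axis=0)
        arr[:, 0] -= arr[:, 0].mean()  # exact by symmetry; kept for clarity
    return arr


@dataclass(frozen=True)
class FaceTemplate:
    """24 named landmarks of a symmetric idealized adult face, centered."""

    coords: np.ndarray  # (24, 3), centroid at origin, midline in plane x=0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.coords[_INDEX[name]]

    @property
    def centroid_size(self) -> float:
        return float(np.sqrt((self.coords ** 2).sum()))


def make_template() -> FaceTemplate:
    """Return the built-in symmetric adult face template."""
    coords = _mirror_field(_TEMPLATE_POINTS, center=False)
    coords = coords - coords.mean(axis=0)
    return FaceTemplate(coords)


def default_sex_effect() -> np.ndarray:
    """Built-in male-direction landmark displacement field (24, 3), mm."""
    return _mirror_field(_SEX_EFFECT_POINTS, center=False)


def _allometry_field() -> np.ndarray:
    arr = _mirror_field(_ALLOMETRY_POINTS, center=False)
    return arr / np.linalg.norm(arr)


# Table-style cohort defaults: (n, mean height cm, height sd cm) per
# (group label, sex) cell of the emulated study population.
_CELLS: dict[tuple[str, str], tuple[int, float, float]] = {
    ("early_childhood", "M"): (98, 110.1, 9.8),
    ("early_childhood", "F"): (95, 109.2, 10.7),
    ("late_childhood", "M"): (128, 141.8, 14.0),
    ("late_childhood", "F"): (118, 141.7, 13.0),
    ("puberty", "M"): (52, 168.9, 9.2),
    ("puberty", "F"): (56, 161.8, 7.0),
    ("adolescence", "M"): (46, 180.3, 9.2),
    ("adolescence", "F"): (65, 166.5, 7.5),
    ("young_adult", "M"): (98, 180.9, 8.4),
    ("young_adult", "F"): (215, 167.0, 6.4),
    ("adult", "M"): (222, 182.2, 7.1),
    ("adult", "F"): (360, 165.7, 6.9),
}

# Per-group face scale relative to adult, tracking typical craniofacial
# growth attainment (~80% of adult size in early childhood).
_GROWTH_CURVE: dict[str, float] = {
    "early_childhood": 0.80,
    "late_childhood": 0.89,
    "puberty": 0.95,
    "adolescence": 0.99,
    "young_adult": 1.00,
    "adult": 1.00,
}

# Caliper base values (adult, mm); simulated as growth- and sex-scaled
# constants plus Gaussian noise (no landmark basis exists for them).
_CALIPER_BASE: dict[str, float] = {
    "maximum_cranial_width": 145.0,
    "minimum_frontal_width": 108.0,
    "maximum_facial_width": 132.0,
    "mandibular_width": 100.0,
    "maximum_cranial_length": 185.0,
}


@dataclass
class SimulationSpec:
    """All dials of the synthetic cohort generator.

    ``sex_effect`` is applied with +1/2 to males and -1/2 to females and
    multiplied by ``effect_scale`` (0 = exchangeable null).  Subject face
    scale is ``growth_curve[group] * (1 + height_size_coupling * dh)``
    where ``dh`` is the subject's relative height deviation from the
    group's (sex-pooled) reference height, so size is linear in height
    and carries no sex information beyond height itself.  The allometric
    term displaces landmarks along a fixed unit field in proportion to
    the subject's centroid-size deviation from the template.
    """

    n_per_cell: dict[tuple[str, str], int]
    height_model: dict[tuple[str, str], tuple[float, float]]  # (mean, sd) cm
    growth_curve: dict[str, float]
    sex_effect: np.ndarray = field(default_factory=default_sex_effect)  # (24,3) mm
    effect_scale: float = 1.0
    allometry_slope: float = 0.02  # mm displacement per mm centroid-size deviation
    noise_sd: float = 0.5  # mm, isotropic per landmark coordinate
    height_size_coupling: float = 0.5  # relative size change per relative height change
    caliper_sex_factor: float = 0.04  # relative male-female caliper difference
    caliper_noise_sd: float = 5.0  # mm, between-subject scatter
    rigid_motion: bool = True  # random device-frame rotation + translation
    seed: int = 20160422

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_cell.values()):
            raise ValueError("cell counts must be non-negative")
        if self.noise_sd < 0 or self.caliper_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if any(g <= 0 for g in self.growth_curve.values()):
            raise ValueError("growth curve factors must be positive")
        if np.asarray(self.sex_effect).shape != (24, 3):
            raise ValueError("sex_effect must be a (24, 3) field")
        for key in self.n_per_cell:
            if key not in self.height_model:
                raise ValueError(f"height_model missing cell {key}")
            if key[0] not in self.growth_curve:
                raise ValueError(f"growth_curve missing group {key[0]}")

    def total_counts(self) -> dict[str, int]:
        totals = {"M": 0, "F": 0}
        for (_, sex), n in self.n_per_cell.items():
            totals[sex] += n
        return totals


def default_spec(**overrides) -> SimulationSpec:
    """Default simulation: study-sized cells and height distributions.

    Cell sizes and height means/SDs follow the emulated study population
    (e.g. 98 early-childhood males averaging 110.1 cm; 360 adult females).
    Keyword overrides replace any :class:`SimulationSpec` field.
    """
    spec = SimulationSpec(
        n_per_cell={cell: n for cell, (n, _, _) in _CELLS.items()},
        height_model={cell: (mean, sd) for cell, (_, mean, sd) in _CELLS.items()},
        growth_curve=dict(_GROWTH_CURVE),
    )
    return replace(spec, **overrides) if overrides else spec


def _sample_heights(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    heights = rng.normal(mean, sd, size=n)
    while np.any(heights <= 0):  # truncate at zero (relevant only for absurd SDs)
        bad = heights <= 0
        heights[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return heights


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Draw one full synthetic cohort from ``spec`` (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    template = make_template()
    allometry = _allometry_field()
    template_cs = template.centroid_size

    subjects: list[SubjectRecord] = []
    configurations: dict[str, LandmarkConfiguration] = {}
    counter = 0
    for group in AGE_GROUPS:
        # sex-pooled reference height, so size|height is sex-free
        cell_means = [
            spec.height_model[(group.label, sex)][0]
            for sex in ("M", "F")
            if (group.label, sex) in spec.n_per_cell
        ]
        ref_height = float(np.mean(cell_means)) if cell_means else 1.0
        for sex in ("M", "F"):
            cell = (group.label, sex)
            n = spec.n_per_cell.get(cell, 0)
            if n == 0:
                continue
            mean_h, sd_h = spec.height_model[cell]
            ages = rng.uniform(group.low, group.high + 1, size=n)
            heights = _sample_heights(rng, n, mean_h, sd_h)
            sign = 0.5 if sex == "M" else -0.5
            base = template.coords + spec.effect_scale * sign * spec.sex_effect
            for age, height in zip(ages, heights):
                counter += 1
                sid = f"S{counter:05d}"
                dh = (height - ref_height) / ref_height
                scale = spec.growth_curve[group.label] * (1.0 + spec.height_size_coupling * dh)
                config = scale * base
                cs = scale * template_cs
                config = config + spec.allometry_slope * (cs - template_cs) * allometry
                if spec.noise_sd > 0:
                    config = config + rng.normal(0.0, spec.noise_sd, size=(24, 3))
                if spec.rigid_motion:
                    rotation = special_ortho_group.rvs(3, random_state=rng)
                    translation = rng.uniform(-100.0, 100.0, size=3)
                    config = config @ rotation.T + translation
                direct = {}
                for name in DIRECT_MEASUREMENT_NAMES:
                    value = (
                        _CALIPER_BASE[name]
                        * scale
                        * (1.0 + spec.effect_scale * spec.caliper_sex_factor * sign)
                    )
                    if spec.caliper_noise_sd > 0:
                        value += rng.normal(0.0, spec.caliper_noise_sd)
                    direct[name] = float(value)
                subjects.append(
                    SubjectRecord(sid, sex, float(age), float(height), direct)
                )
                configurations[sid] = LandmarkConfiguration(sid, config)
    return Cohort(subjects, configurations)


def spec_from_mapping(mapping: Mapping | None) -> SimulationSpec:
    """Build a spec from a (YAML-loaded) mapping; omitted fields default.

    ``n_per_cell`` and ``height_model`` are nested ``{group: {sex: ...}}``
    mappings; ``growth_curve`` maps group label to scale; scalar fields
    are taken verbatim.
    """
    mapping = dict(mapping or {})
    spec = default_spec()
    if "n_per_cell" in mapping:
        spec.n_per_cell = {
            (group, sex): int(n)
            for group, by_sex in mapping.pop("n_per_cell").items()
            for sex, n in by_sex.items()
        }
    if "height_model" in mapping:
        spec.height_model = {
            (group, sex): (float(pair[0]), float(pair[1]))
            for group, by_sex in mapping.pop("height_model").items()
            for sex, pair in by_sex.items()
        }
    if "growth_curve" in mapping:
        spec.growth_curve = {
            group: float(v) for group, v in mapping.pop("growth_curve").items()
        }
    if "sex_effect" in mapping:
        spec.sex_effect = np.asarray(mapping.pop("sex_effect"), dtype=float)
    scalar_fields = {
        "effect_scale", "allometry_slope", "noise_sd", "height_size_coupling",
        "caliper_sex_factor", "caliper_noise_sd", "rigid_motion", "seed",
    }
    unknown = set(mapping) - scalar_fields
    if unknown:
        raise ValueError(f"unknown simulation spec field(s): {sorted(unknown)}")
    for key, value in mapping.items():
        setattr(spec, key, type(getattr(spec, key))(value))
    spec.validate()
    return spec
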