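"""Domain types and CSV I/O for craniofacial cohorts.

A cohort couples one demographic/caliper record per subject with an
optional configuration of 24 named soft-tissue landmarks digitized in 3D.
Subjects are binned into six age groups (early childhood through adult)
covering ages 3-25 in completed years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LANDMARK_NAMES",
    "MIDLINE_LANDMARKS",
    "BILATERAL_PAIRS",
    "DIRECT_MEASUREMENT_NAMES",
    "AgeGroup",
    "AGE_GROUPS",
    "LandmarkConfiguration",
    "SubjectRecord",
    "Cohort",
    "assign_age_group",
    "load_cohort",
    "write_cohort",
]

#: The 24 standard facial soft-tissue landmark codes, in fixed file order.
#: Midline: nasion (n), pronasale (prn), subnasale (sn), labiale superius
#: (ls), stomion (sto), labiale inferius (li), sublabiale (sl), gnathion
#: (gn).  Bilateral (_r/_l): endocanthion (en), exocanthion (ex), alare
#: (al), subalare (sbal), crista philtri (cph), chelion (ch), alar
#: curvature point (ac), tragion (t).
LANDMARK_NAMES: tuple[str, ...] = (
    "n", "prn", "sn", "ls", "sto", "li", "sl", "gn",
    "en_r", "en_l", "ex_r", "ex_l", "al_r", "al_l", "sbal_r", "sbal_l",
    "cph_r", "cph_l", "ch_r", "ch_l", "ac_r", "ac_l", "t_r", "t_l",
)

MIDLINE_LANDMARKS: tuple[str, ...] = ("n", "prn", "sn", "ls", "sto", "li", "sl", "gn")

BILATERAL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (f"{stem}_r", f"{stem}_l")
    for stem in ("en", "ex", "al", "sbal", "cph", "ch", "ac", "t")
)

_LANDMARK_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}

#: Caliper measurements carried on the subject record (spreading calipers;
#: their defining landmarks are not part of the 24-landmark set, so these
#: can only be supplied as direct inputs).
DIRECT_MEASUREMENT_NAMES: tuple[str, ...] = (
    "maximum_cranial_width",
    "minimum_frontal_width",
    "maximum_facial_width",
    "mandibular_width",
    "maximum_cranial_length",
)

_SUBJECT_CSV_COLUMNS = [
    "subject_id", "sex", "age_years", "height_cm",
    "max_cranial_width_mm", "min_frontal_width_mm", "max_facial_width_mm",
    "mandibular_width_mm", "max_cranial_length_mm",
]

_CSV_TO_DIRECT = dict(
    zip(_SUBJECT_CSV_COLUMNS[4:], DIRECT_MEASUREMENT_NAMES, strict=True)
)
_DIRECT_TO_CSV = {v: k for k, v in _CSV_TO_DIRECT.items()}


@dataclass(frozen=True)
class AgeGroup:
    """An inclusive integer year range, e.g. early childhood = ages 3-6."""

    label: str
    low: int
    high: int

    def contains(self, age: float) -> bool:
        return self.low <= math.floor(age) <= self.high

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label} ({self.low}-{self.high})"


#: The six age groups partition integer ages 3..25 with no gap or overlap.
AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("early_childhood", 3, 6),
    AgeGroup("late_childhood", 7, 12),
    AgeGroup("puberty", 13, 15),
    AgeGroup("adolescence", 16, 18),
    AgeGroup("young_adult", 19, 21),
    AgeGroup("adult", 22, 25),
)

AGE_GROUP_BY_LABEL = {g.label: g for g in AGE_GROUPS}
ADULT_GROUP = AGE_GROUP_BY_LABEL["adult"]


def assign_age_group(age: float) -> AgeGroup:
    """Map a decimal age in years to its age group.

    Membership uses completed years: ``floor(age)`` is located in the
    inclusive integer ranges, so e.g. 6.9 is still early childhood.

    Raises
    ------
    ValueError
        If ``age`` is outside the study range [3, 26).
    """
    if not np.isfinite(age) or age < 3 or age >= 26:
        raise ValueError(f"age {age!r} outside the study range [3, 26)")
    year = math.floor(age)
    for group in AGE_GROUPS:
        if group.low <= year <= group.high:
            return group
    raise AssertionError("unreachable: age groups partition 3..25")


class CohortValidationError(ValueError):
    """Raised when a cohort or one of its components fails validation."""


@dataclass
class LandmarkConfiguration:
    """The 24 named landmarks of one subject, xyz in mm (device frame)."""

    subject_id: str
    coords: np.ndarray  # (24, 3) float, ordered as LANDMARK_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (24, 3):
            raise CohortValidationError(
                f"subject {self.subject_id}: expected 24x3 landmark array, "
                f"got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise CohortValidationError(
                f"subject {self.subject_id}: non-finite landmark coordinate"
            )
        # 3D rotation fitting needs a genuinely 3D (non-coplanar) point set.
        centered = self.coords - self.coords.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
            raise CohortValidationError(
                f"subject {self.subject_id}: landmarks are coplanar or degenerate"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.coords[_LANDMARK_INDEX[name]]
        except KeyError:
            raise KeyError(f"unknown landmark code {name!r}") from None

    @classmethod
    def from_points(cls, subject_id: str, points: Mapping[str, Iterable[float]]) -> "LandmarkConfiguration":
        missing = set(LANDMARK_NAMES) - set(points)
        extra = set(points) - set(LANDMARK_NAMES)
        if missing or extra:
            raise CohortValidationError(
                f"subject {subject_id}: landmark set mismatch "
                f"(missing {sorted(missing)}, unknown {sorted(extra)})"
            )
        coords = np.array([points[name] for name in LANDMARK_NAMES], dtype=float)
        return cls(subject_id, coords)


@dataclass
class SubjectRecord:
    """Demographics plus the five optional caliper distances (mm)."""

    subject_id: str
    sex: str  # "M" or "F"
    age: float  # decimal years, 3 <= age < 26
    height: float  # cm
    direct_measurements: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise CohortValidationError(
                f"subject {self.subject_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )
        if not (3 <= self.age < 26):
            raise CohortValidationError(
                f"subject {self.subject_id}: age {self.age} outside [3, 26)"
            )
        if not (np.isfinite(self.height) and self.height > 0):
            raise CohortValidationError(
                f"subject {self.subject_id}: height must be finite and positive, "
                f"got {self.height}"
            )
        unknown = set(self.direct_measurements) - set(DIRECT_MEASUREMENT_NAMES)
        if unknown:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown direct measurements {sorted(unknown)}"
            )

    @property
    def age_group(self) -> AgeGroup:
        return assign_age_group(self.age)


@dataclass
class Cohort:
    """Subjects plus landmark configurations keyed by subject id."""

    subjects: list[SubjectRecord]
    configurations: dict[str, LandmarkConfiguration]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject_id(s): {dupes}")
        orphans = set(self.configurations) - set(ids)
        if orphans:
            raise CohortValidationError(
                f"landmark configurations without subject records: {sorted(orphans)}"
            )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def unlandmarked_ids(self) -> list[str]:
        """Subjects retained for caliper-only analyses (no landmark row)."""
        return [s.subject_id for s in self.subjects if s.subject_id not in self.configurations]

    def subset(self, group: AgeGroup) -> "Cohort":
        kept = [s for s in self.subjects if s.age_group == group]
        ids = {s.subject_id for s in kept}
        return Cohort(kept, {i: c for i, c in self.configurations.items() if i in ids})

    def landmark_array(self, subject_ids: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Stack configurations into an (n, 24, 3) array, preserving order."""
        if subject_ids is None:
            subject_ids = [i for i in self.subject_ids if i in self.configurations]
        arr = np.stack([self.configurations[i].coords for i in subject_ids])
        return subject_ids, arr


# ---------------------------------------------------------------------------
# CSV I/O

def _landmark_columns() -> list[str]:
    return [f"{code}_{axis}" for code in LANDMARK_NAMES for axis in "xyz"]


class CohortParseError(ValueError):
    """Raised on malformed cohort CSV input, naming the offending location."""


def load_cohort(subjects_path: str | Path, landmarks_path: str | Path) -> Cohort:
    """Read and validate ``subjects.csv`` + ``landmarks.csv``.

    Subjects lacking a landmark row are retained (caliper-only analyses)
    and reported by :meth:`Cohort.unlandmarked_ids`.
    """
    subj = pd.read_csv(subjects_path, dtype={"subject_id": str})
    missing_cols = [c for c in _SUBJECT_CSV_COLUMNS if c not in subj.columns]
    if missing_cols:
        raise CohortParseError(
            f"{subjects_path}: missing column(s) {missing_cols}"
        )
    if subj["subject_id"].duplicated().any():
        dupes = sorted(subj.loc[subj["subject_id"].duplicated(), "subject_id"])
        raise CohortParseError(f"{subjects_path}: duplicate subject_id(s) {dupes}")

    subjects = []
    for row in subj.itertuples(index=False):
        direct = {}
        for col, name in _CSV_TO_DIRECT.items():
            value = getattr(row, col)
            if value is not None and np.isfinite(value):
                direct[name] = float(value)
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=row.subject_id,
                    sex=str(row.sex),
                    age=float(row.age_years),
                    height=float(row.height_cm),
                    direct_measurements=direct,
                )
            )
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"{subjects_path}: subject {row.subject_id}: {exc}") from exc

    lmk = pd.read_csv(landmarks_path, dtype={"subject_id": str})
    wanted = _landmark_columns()
    missing_cols = [c for c in wanted if c not in lmk.columns]
    if missing_cols:
        raise CohortParseError(f"{landmarks_path}: missing column(s) {missing_cols}")
    if lmk["subject_id"].duplicated().any():
        dupes = sorted(lmk.loc[lmk["subject_id"].duplicated(), "subject_id"])
        raise CohortParseError(f"{landmarks_path}: duplicate subject_id(s) {dupes}")

    configurations = {}
    for _, row in lmk.iterrows():
        sid = row["subject_id"]
        values = row[wanted].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise CohortParseError(
                f"{landmarks_path}: subject {sid}: non-numeric coordinate in "
                f"column {wanted[bad[0]]}"
            )
        configurations[sid] = LandmarkConfiguration(sid, values.reshape(24, 3))

    try:
        return Cohort(subjects, configurations)
    except CohortValidationError as exc:
        raise CohortParseError(str(exc)) from exc


def write_cohort(cohort: Cohort, subjects_path: str | Path, landmarks_path: str | Path) -> None:
    """Write a cohort back to the two-CSV on-disk form (load∘write = id)."""
    rows = []
    for s in cohort.subjects:
        row = {
            "subject_id": s.subject_id,
            "sex": s.sex,
            "age_years": s.age,
            "height_cm": s.height,
        }
        for name, col in _DIRECT_TO_CSV.items():
            row[col] = s.direct_measurements.get(name, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=_SUBJECT_CSV_COLUMNS).to_csv(
        subjects_path, index=False, float_format="%.6f"
    )

    cols = _landmark_columns()
    lrows = []
    for sid in cohort.subject_ids:
        config = cohort.configurations.get(sid)
        if config is None:
            continue
        lrows.append({"subject_id": sid, **dict(zip(cols, config.coords.ravel()))})
    pd.DataFrame(lrows, columns=["subject_id", *cols]).to_csv(
        landmarks_path, index=False, float_format="%.6f"
    )
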