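"""The 29 traditional craniofacial anthropometric measurements.

24 are interlandmark Euclidean distances derived from the 3D landmark
configuration; 5 (the spreading-caliper distances) are passed through
from the subject record because their defining landmarks (euryon,
frontotemporale, zygion, gonion, glabella, opisthocranion) are not in
the 24-landmark set.  Bilateral derived measurements use the left side
only (palpebral fissure length, nasal ala length, the three facial
depths), except cranial base width which spans both tragions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, DIRECT_MEASUREMENT_NAMES, LandmarkConfiguration

__all__ = [
    "MeasurementDefinition",
    "MEASUREMENTS",
    "MEASUREMENT_NAMES",
    "REGIONS",
    "interlandmark_distance",
    "compute_measurements",
    "region_of",
]


@dataclass(frozen=True)
class MeasurementDefinition:
    name: str
    region: str  # cranium | face | eye | nose | mouth
    landmarks: tuple[str, str] | None  # None for direct caliper input

    @property
    def is_direct(self) -> bool:
        return self.landmarks is None


def _d(name: str, region: str, a: str, b: str) -> MeasurementDefinition:
    return MeasurementDefinition(name, region, (a, b))


#: All 29 measurements in canonical order: the 5 direct caliper distances
#: first, then the 24 landmark-derived distances.
MEASUREMENTS: tuple[MeasurementDefinition, ...] = (
    MeasurementDefinition("maximum_cranial_width", "cranium", None),
    MeasurementDefinition("minimum_frontal_width", "cranium", None),
    MeasurementDefinition("maximum_facial_width", "face", None),
    MeasurementDefinition("mandibular_width", "face", None),
    MeasurementDefinition("maximum_cranial_length", "cranium", None),
    _d("cranial_base_width", "cranium", "t_r", "t_l"),
    _d("upper_facial_depth", "face", "n", "t_l"),
    _d("middle_facial_depth", "face", "sn", "t_l"),
    _d("lower_facial_depth", "face", "gn", "t_l"),
    _d("morphological_facial_height", "face", "n", "gn"),
    _d("upper_facial_height", "face", "n", "sto"),
    _d("lower_facial_height", "face", "sn", "gn"),
    _d("intercanthal_width", "eye", "en_r", "en_l"),
    _d("outercanthal_width", "eye", "ex_r", "ex_l"),
    _d("palpebral_fissure_length", "eye", "en_l", "ex_l"),
    _d("nasal_width", "nose", "al_r", "al_l"),
    _d("subnasal_width", "nose", "sbal_r", "sbal_l"),
    _d("nasal_protrusion", "nose", "sn", "prn"),
    _d("nasal_ala_length", "nose", "ac_l", "prn"),
    _d("nasal_height", "nose", "n", "sn"),
    _d("nasal_bridge_length", "nose", "n", "prn"),
    _d("labial_fissure_width", "mouth", "ch_r", "ch_l"),
    _d("philtrum_width", "mouth", "cph_r", "cph_l"),
    _d("philtrum_length", "mouth", "sn", "ls"),
    _d("upper_lip_height", "mouth", "sn", "sto"),
    _d("lower_lip_height", "mouth", "sto", "sl"),
    _d("upper_vermilion_height", "mouth", "ls", "sto"),
    _d("lower_vermilion_height", "mouth", "sto", "li"),
    _d("cutaneous_lower_lip_height", "mouth", "li", "sl"),
)

MEASUREMENT_NAMES: tuple[str, ...] = tuple(m.name for m in MEASUREMENTS)
REGIONS: tuple[str, ...] = ("cranium", "face", "eye", "nose", "mouth")

_BY_NAME = {m.name: m for m in MEASUREMENTS}

assert len(MEASUREMENTS) == 29
assert sum(m.is_direct for m in MEASUREMENTS) == 5
assert set(m.name for m in MEASUREMENTS if m.is_direct) == set(DIRECT_MEASUREMENT_NAMES)


def region_of(name: str) -> str:
    """Craniofacial region of a measurement (head-region names → cranium)."""
    try:
        return _BY_NAME[name].region
    except KeyError:
        raise KeyError(f"unknown measurement name {name!r}") from None


def interlandmark_distance(config: LandmarkConfiguration, a: str, b: str) -> float:
    """Euclidean distance in mm between two named landmarks."""
    return float(np.linalg.norm(config[a] - config[b]))


def compute_measurements(cohort: Cohort) -> pd.DataFrame:
    """Per-subject table of all 29 measurements (mm).

    Rows are indexed by subject_id in cohort order.  Derived measurements
    are present whenever the subject has a landmark configuration; direct
    ones are copied from the subject record and NaN where missing.
    """
    rows = []
    for subject in cohort.subjects:
        row: dict[str, float] = {}
        config = cohort.configurations.get(subject.subject_id)
        for m in MEASUREMENTS:
            if m.is_direct:
                row[m.name] = subject.direct_measurements.get(m.name, np.nan)
            elif config is not None:
                row[m.name] = interlandmark_distance(config, *m.landmarks)
            else:
                row[m.name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(cohort.subject_ids, name="subject_id"),
                        columns=list(MEASUREMENT_NAMES))
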