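"""TIL density computation and high/low dichotomization.

Densities are measured as cells/mm² in four marker-compartment combinations:
CD3 and CD8 counted in the tumor core (CT) and at the invasive margin (IM).
Each compartment density is the arithmetic mean of the per-area densities of
a small number of non-contiguous high-density fields (three by default);
averaging several fields damps sampling error from the spatial heterogeneity
of the infiltrate.

The dichotomization convention is fixed throughout the package: a density is
called "high" when it is *strictly greater* than the cutoff, and "low" when
it is less than or equal to it. Ties therefore go to "low".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: canonical column order for the four marker-compartment densities
COMPARTMENTS: tuple[str, ...] = ("cd3_ct", "cd3_im", "cd8_ct", "cd8_im")

HIGH = "high"
LOW = "low"


class Marker(str, Enum):
    CD3 = "CD3"
    CD8 = "CD8"


class Region(str, Enum):
    CT = "CT"
    IM = "IM"


@dataclass(frozen=True)
class RegionMeasurement:
    """Raw cell counts for one marker in one compartment of one specimen.

    ``area_counts[i]`` is the number of stained cells in the i-th selected
    field and ``area_mm2[i]`` its area. Field order carries no meaning.
    """

    patient_id: str
    marker: Marker
    region: Region
    area_counts: Sequence[int]
    area_mm2: Sequence[float]
    expected_areas: int = 3

    def __post_init__(self) -> None:
        if len(self.area_counts) != len(self.area_mm2):
            raise DataError(
                f"{self.patient_id}: {len(self.area_counts)} counts but "
                f"{len(self.area_mm2)} areas"
            )
        if len(self.area_counts) == 0:
            raise DataError(f"{self.patient_id}: no areas measured")
        if any(c < 0 for c in self.area_counts):
            raise DataError(f"{self.patient_id}: negative cell count")
        if any(a <= 0 for a in self.area_mm2):
            raise DataError(f"{self.patient_id}: non-positive field area")

    @property
    def compartment(self) -> str:
        return f"{self.marker.value.lower()}_{self.region.value.lower()}"


@dataclass(frozen=True)
class MarkerCall:
    """A dichotomized density: one compartment of one patient, high or low."""

    patient_id: str
    compartment: str
    call: str  # "high" | "low"
    cutoff_used: float

    def __post_init__(self) -> None:
        if self.call not in (HIGH, LOW):
            raise DataError(f"invalid call {self.call!r}")


def compute_density(m: RegionMeasurement) -> float:
    """Mean per-field density (cells/mm²) for one measurement.

    The estimator is the arithmetic mean of the per-field densities
    ``count_i / area_i`` — not the pooled ``sum(counts)/sum(areas)``; the two
    coincide when all fields share the same area. Fewer fields than
    ``expected_areas`` are accepted with a warning (the available fields are
    averaged).
    """
    if len(m.area_counts) < m.expected_areas:
        logger.warning(
            "%s %s: only %d of %d fields measured; averaging what exists",
            m.patient_id, m.compartment, len(m.area_counts), m.expected_areas,
        )
    per_area = [c / a for c, a in zip(m.area_counts, m.area_mm2)]
    return float(np.mean(per_area))


def dichotomize(density: float, cutoff: float):
    """Classify a density against a cutoff: ``high`` iff density > cutoff.

    Missing densities (None/NaN) propagate as missing (returns NaN) — they
    are never imputed. Negative inputs are rejected.
    """
    if density is None or (isinstance(density, float) and math.isnan(density)):
        return float("nan")
    if density < 0:
        raise DataError(f"negative density {density}")
    if cutoff < 0:
        raise DataError(f"negative cutoff {cutoff}")
    return HIGH if density > cutoff else LOW


def dichotomize_series(densities: pd.Series, cutoff: float) -> pd.Series:
    """Vectorized :func:`dichotomize`; NaNs stay missing."""
    d = pd.to_numeric(densities, errors="coerce")
    if (d < 0).any():
        raise DataError("negative density in input")
    if cutoff < 0:
        raise DataError(f"negative cutoff {cutoff}")
    out = pd.Series(pd.NA, index=densities.index, dtype="object")
    out[d > cutoff] = HIGH
    out[d <= cutoff] = LOW
    return out


def add_marker_calls(
    cohort: pd.DataFrame, cutoffs: Mapping[str, float]
) -> pd.DataFrame:
    """Append a ``<compartment>_call`` column per compartment to a cohort table."""
    out = cohort.copy()
    for comp in COMPARTMENTS:
        if comp not in cutoffs:
            raise ConfigurationError(f"no cutoff supplied for {comp}")
        if comp not in out.columns:
            raise DataError(f"cohort has no density column {comp!r}")
        out[f"{comp}_call"] = dichotomize_series(out[comp], float(cutoffs[comp]))
    return out


def densities_from_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format measurement table into wide per-patient densities.

    Expected columns: patient_id, marker (CD3/CD8), region (CT/IM),
    area_index, count, area_mm2. Returns one row per patient with the four
    compartment density columns (missing compartments stay NaN).
    """
    required = {"patient_id", "marker", "region", "count", "area_mm2"}
    missing = required - set(measurements.columns)
    if missing:
        raise DataError(f"measurement table lacks columns: {sorted(missing)}")

    records: dict[str, dict[str, float]] = {}
    grouped = measurements.groupby(["patient_id", "marker", "region"], sort=True)
    for (pid, marker, region), grp in grouped:
        m = RegionMeasurement(
            patient_id=str(pid),
            marker=Marker(str(marker).upper()),
            region=Region(str(region).upper()),
            area_counts=grp["count"].tolist(),
            area_mm2=grp["area_mm2"].tolist(),
        )
        records.setdefault(str(pid), {})[m.compartment] = compute_density(m)

    rows = []
    for pid in sorted(records):
        row: dict[str, object] = {"patient_id": pid}
        for comp in COMPARTMENTS:
            row[comp] = records[pid].get(comp, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", *COMPARTMENTS])
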