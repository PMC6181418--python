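"""Immunoscore assignment (I0-I4).

The Immunoscore of a specimen is the number of marker-compartment densities
classified "high" among CD3 and CD8 in the tumor core and at the invasive
margin: I4 when all four are high, I0 when all four are low, and the count
of highs in between (the standard Galon counting rule). Patients with any
missing compartment call get an undefined grade with an explicit missing
flag — never an imputed one — and are excluded from Immunoscore survival
analyses (complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .density import COMPARTMENTS, HIGH, LOW, add_marker_calls
from .errors import ConfigurationError, DataError

__all__ = ["ImmunoscoreGrade", "assign_immunoscore", "score_cohort"]


@dataclass(frozen=True)
class ImmunoscoreGrade:
    patient_id: str
    grade: int | None  # None when any call is missing
    calls: Mapping[str, str | None]
    n_missing_calls: int

    @property
    def defined(self) -> bool:
        return self.n_missing_calls == 0


def assign_immunoscore(
    calls: Mapping[str, str | None], patient_id: str = ""
) -> ImmunoscoreGrade:
    """Grade = number of "high" calls among the four compartments.

    ``calls`` maps each compartment name (cd3_ct, cd3_im, cd8_ct, cd8_im)
    to "high", "low" or None/NaN (missing). A single missing compartment
    makes the grade undefined.
    """
    missing = 0
    n_high = 0
    normalized: dict[str, str | None] = {}
    for comp in COMPARTMENTS:
        call = calls.get(comp)
        if isinstance(call, str):
            call = call.lower()
        if call in (HIGH, LOW):
            normalized[comp] = call
            n_high += call == HIGH
        elif call is None or pd.isna(call):
            normalized[comp] = None
            missing += 1
        else:
            raise DataError(f"invalid call {call!r} for {comp}")
    return ImmunoscoreGrade(
        patient_id=patient_id,
        grade=None if missing else n_high,
        calls=normalized,
        n_missing_calls=missing,
    )


def score_cohort(
    cohort: pd.DataFrame, cutoffs: Mapping[str, float]
) -> pd.DataFrame:
    """Dichotomize the four density columns and append call + score columns.

    Returns a copy of the cohort with ``<compartment>_call`` columns and a
    nullable-integer ``immunoscore`` column (NA where any density is
    missing). Requires a cutoff for every compartment.
    """
    for comp in COMPARTMENTS:
        if comp not in cutoffs:
            raise ConfigurationError(f"no cutoff supplied for {comp}")
    out = add_marker_calls(cohort, cutoffs)
    if len(out) == 0:
        out["immunoscore"] = pd.Series(dtype="Int64")
        return out
    call_cols = out[[f"{c}_call" for c in COMPARTMENTS]]
    n_high = (call_cols == HIGH).sum(axis=1)
    any_missing = call_cols.isna().any(axis=1)
    out["immunoscore"] = n_high.astype("Int64").mask(any_missing)
    return out
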