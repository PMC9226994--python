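"""Core subject-level containers.

A :class:`SubjectProfile` holds one subject's group label, demographics and
the percentage of each measured immune subset (a missing measurement is
simply absent from, or ``None`` in, the ``values`` map — never zero).
:class:`LongitudinalRecord` holds one patient-week of a monitored course:
the SLEDAI-2K disease-activity score, an optional leucocyte count, and
subset percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

GROUP_SLE = "SLE"
GROUP_HC = "HC"


@dataclass
class SubjectProfile:
    subject_id: str
    group: str  # "SLE" or "HC"
    sex: str | None = None  # "F"/"M"
    age: float | None = None  # years
    values: dict[str, float | None] = field(default_factory=dict)

    def value(self, subset: str) -> float | None:
        """Return the subset percentage, or None when missing."""
        v = self.values.get(subset)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)


@dataclass
class LongitudinalRecord:
    patient_id: str
    week: int
    sledai2k: int  # SLEDAI-2K disease-activity score, >= 0
    leucocyte_count: float | None = None  # x10^9 cells/L
    values: dict[str, float] = field(default_factory=dict)


def split_by_group(
    profiles: list[SubjectProfile],
) -> tuple[list[SubjectProfile], list[SubjectProfile]]:
    """Return (SLE profiles, HC profiles) preserving input order."""
    sle = [p for p in profiles if p.group == GROUP_SLE]
    hc = [p for p in profiles if p.group == GROUP_HC]
    return sle, hc


def subset_values(
    profiles: list[SubjectProfile], subset: str
) -> list[float]:
    """Non-missing values of one subset across profiles, input order."""
    out = []
    for p in profiles:
        v = p.value(subset)
        if v is not None:
            out.append(v)
    return out


def panel_names(profiles: list[SubjectProfile]) -> list[str]:
    """Sorted union of subset names seen in a cohort."""
    names: set[str] = set()
    for p in profiles:
        names.update(p.values.keys())
    return sorted(names)
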