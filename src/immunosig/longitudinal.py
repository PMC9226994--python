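"""Per-patient trajectory analysis of monitored treatment courses.

Each monitored patient contributes a handful of timepoints (weeks 0, 4 and
12 by default), so only the weakest association measure is defensible:
a Spearman rank correlation (midrank ties) between a subset's percentage
and the SLEDAI-2K disease-activity score, reported per patient and
labelled qualitatively.  Per-patient correlations are tallied across the
cohort, never averaged: a 3-point rho is a direction indicator, not an
estimate worth pooling.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

from scipy import stats as sps

from .errors import InsufficientDataError
from .profiles import LongitudinalRecord

#: |rho| below this is labelled "none"; 0.5 keeps a 3-point monotone
#: series with one tie (rho ~ 0.866) in the labelled class.
DIRECTION_THRESHOLD = 0.5
MIN_TIMEPOINTS = 3


@dataclass
class TrajectoryAssociation:
    patient_id: str
    subset: str
    rho: float  # NaN when undefined (zero-variance series)
    direction: str  # "positive" | "negative" | "none"


def _label(rho: float, threshold: float) -> str:
    if math.isnan(rho) or abs(rho) < threshold:
        return "none"
    return "positive" if rho > 0 else "negative"


def spearman_trajectory(
    records: list[LongitudinalRecord],
    subset: str,
    threshold: float = DIRECTION_THRESHOLD,
) -> TrajectoryAssociation:
    """Spearman correlation between one patient's subset percentages and
    SLEDAI-2K across weeks.

    Requires >= 3 timepoints with both quantities present.  A zero-variance
    series leaves rho undefined (NaN) and the direction "none".
    """
    pairs = [
        (r.week, float(r.sledai2k), float(r.values[subset]))
        for r in records
        if subset in r.values
    ]
    if len(pairs) < MIN_TIMEPOINTS:
        pid = records[0].patient_id if records else "?"
        raise InsufficientDataError(
            f"patient {pid!r}, subset {subset!r}: need >= {MIN_TIMEPOINTS} "
            f"timepoints, got {len(pairs)}"
        )
    pairs.sort(key=lambda t: t[0])
    sledai = [p[1] for p in pairs]
    pct = [p[2] for p in pairs]
    if len(set(sledai)) == 1 or len(set(pct)) == 1:
        rho = float("nan")
    else:
        rho = float(sps.spearmanr(pct, sledai).statistic)
    return TrajectoryAssociation(
        patient_id=records[0].patient_id,
        subset=subset,
        rho=rho,
        direction=_label(rho, threshold),
    )


def compute_associations(
    records: list[LongitudinalRecord],
    subsets: list[str] | None = None,
    threshold: float = DIRECTION_THRESHOLD,
) -> tuple[list[TrajectoryAssociation], list[str]]:
    """All per-patient associations; skips short series with a warning."""
    by_patient: dict[str, list[LongitudinalRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    if subsets is None:
        names: set[str] = set()
        for r in records:
            names.update(r.values.keys())
        subsets = sorted(names)
    out: list[TrajectoryAssociation] = []
    warnings: list[str] = []
    for pid in sorted(by_patient):
        for subset in subsets:
            try:
                out.append(spearman_trajectory(by_patient[pid], subset, threshold))
            except InsufficientDataError as exc:
                warnings.append(str(exc))
    return out, warnings


def cohort_trajectory_summary(
    associations: list[TrajectoryAssociation],
) -> dict[str, dict[str, int]]:
    """Per-subset tally of direction labels across patients."""
    if not associations:
        raise InsufficientDataError("no associations to summarise")
    tally: dict[str, dict[str, int]] = {}
    for a in associations:
        t = tally.setdefault(a.subset, {"positive": 0, "negative": 0, "none": 0})
        t[a.direction] += 1
    return tally


def load_monitored_patients() -> list[LongitudinalRecord]:
    """Bundled example course of four treated patients (disease-activity
    score and leucocyte count only; no subset percentages)."""
    records = []
    path = resources.files("immunosig.data") / "monitored_patients.csv"
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                LongitudinalRecord(
                    patient_id=row["patient_id"],
                    week=int(row["week"]),
                    sledai2k=int(row["sledai2k"]),
                    leucocyte_count=float(row["leucocyte_count"]),
                )
            )
    return records
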