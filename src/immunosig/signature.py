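"""Zero zones, decile-distance ranks and the per-subject immune signature
(parts 2-3 of the algorithm).

For each subset, candidate symmetric ranges AVG +- n*SD/10 (n = 0..n_max)
are scored by the *cover-ratio difference*: the fraction of healthy
controls inside the range minus the fraction of SLE subjects inside it.
The smallest n maximizing that difference defines the subset's *zero zone*
— the range where a value is considered reference-typical and scores 0.

A value outside the zone is ranked by its distance to the nearest zone
boundary measured in SD/10 steps: 1-10 steps (up to one SD) -> -1,
11-20 steps -> -2, 21 or more -> -3.  Boundaries are inclusive toward the
less negative rank.  A subject's immune signature is the sum of its ranks
over all usable subsets, so 0 means fully reference-typical and more
negative means more deviant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, InsufficientDataError
from .profiles import SubjectProfile, panel_names, split_by_group, subset_values
from .reference import (
    MIN_HC_VALUES,
    QUANTILE_CONVENTION,
    ReferenceStats,
    fit_reference,
)

DEFAULT_N_MAX = 50
DEFAULT_BAND_STEPS = 10  # SD/10 steps per rank band
DEFAULT_RANK_FLOOR = -3
_REL_EPS = 1e-9  # guards band boundaries against float round-off


@dataclass
class CoverCurve:
    """Audit trail of the zero-zone search for one subset."""

    subset: str
    step: float  # SD/10 in percentage points
    n_values: np.ndarray  # 0..n_max
    cover_hc: np.ndarray  # fraction of HC inside AVG +- n*step
    cover_sle: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.cover_hc - self.cover_sle


@dataclass
class ZeroZone:
    subset: str
    n_star: int
    lower: float
    upper: float


@dataclass
class RankAssignment:
    subject_id: str
    subset: str
    deviation_steps: int  # 0 inside the zone
    rank: int  # 0, -1, -2 or -3


@dataclass
class SignatureResult:
    subject_id: str
    group: str
    ranks: dict[str, int]
    score: int  # the immune signature: sum of ranks
    n_subsets_used: int
    n_subsets_skipped: int


@dataclass
class SubsetModel:
    stats: ReferenceStats
    zone: ZeroZone


@dataclass
class ReferenceModel:
    """Fitted artifacts for every usable subset plus the fitting decisions."""

    subsets: dict[str, SubsetModel]
    skipped: dict[str, str] = field(default_factory=dict)  # subset -> reason
    n_max: int = DEFAULT_N_MAX
    band_steps: int = DEFAULT_BAND_STEPS
    rank_floor: int = DEFAULT_RANK_FLOOR
    quantile_convention: str = QUANTILE_CONVENTION
    cover_on_cleaned: bool = False  # cover ratios use raw HC values by default


def cover_ratio(values, avg: float, sd: float, n: int) -> float:
    """Fraction of values inside AVG +- n*SD/10, bounds inclusive."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DataError("cover_ratio: empty value list")
    half = n * sd / 10.0
    return float(np.mean(np.abs(arr - avg) <= half))


def determine_zero_zone(
    hc_values,
    sle_values,
    ref: ReferenceStats,
    n_max: int = DEFAULT_N_MAX,
) -> tuple[ZeroZone, CoverCurve]:
    """Pick the zero zone: smallest n maximizing cover_hc(n) - cover_sle(n)."""
    if ref.degenerate or not ref.sd > 0:
        raise DataError(f"subset {ref.subset!r}: degenerate SD, no zero zone")
    hc = np.asarray(list(hc_values), dtype=float)
    sle = np.asarray(list(sle_values), dtype=float)
    if hc.size == 0 or sle.size == 0:
        raise InsufficientDataError(
            f"subset {ref.subset!r}: both groups must be nonempty for zero-zone search"
        )
    step = ref.sd / 10.0
    ns = np.arange(n_max + 1)
    halves = ns * step
    # broadcast: (n_max+1, n_values) inclusion tables
    ch = (np.abs(hc - ref.avg)[None, :] <= halves[:, None]).mean(axis=1)
    cs = (np.abs(sle - ref.avg)[None, :] <= halves[:, None]).mean(axis=1)
    diff = ch - cs
    n_star = int(np.argmax(diff))  # argmax returns the first (smallest) maximizer
    zone = ZeroZone(
        subset=ref.subset,
        n_star=n_star,
        lower=ref.avg - n_star * step,
        upper=ref.avg + n_star * step,
    )
    curve = CoverCurve(subset=ref.subset, step=step, n_values=ns, cover_hc=ch, cover_sle=cs)
    return zone, curve


def rank_value(
    value: float,
    zone: ZeroZone,
    ref: ReferenceStats,
    band_steps: int = DEFAULT_BAND_STEPS,
    rank_floor: int = DEFAULT_RANK_FLOOR,
    subject_id: str = "",
) -> RankAssignment:
    """Rank one value against a subset's zero zone.

    Inside the zone (inclusive) -> 0.  Otherwise the distance d to the
    nearest boundary is converted to k = ceil(d / (SD/10)) deviation steps
    and banded: ``band_steps`` steps per unit of rank down to the floor.
    A value exactly on a band boundary takes the less negative rank.
    """
    if not ref.sd > 0:
        raise DataError(f"subset {ref.subset!r}: degenerate SD, cannot rank")
    v = float(value)
    if zone.lower <= v <= zone.upper:
        return RankAssignment(subject_id, ref.subset, 0, 0)
    d = max(zone.lower - v, v - zone.upper)
    step = ref.sd / 10.0
    k = max(1, math.ceil(d / step - _REL_EPS))
    band = (k - 1) // band_steps + 1
    rank = -min(band, -rank_floor)
    return RankAssignment(subject_id, ref.subset, k, rank)


def fit_signature_model(
    profiles: list[SubjectProfile],
    n_max: int = DEFAULT_N_MAX,
    band_steps: int = DEFAULT_BAND_STEPS,
    rank_floor: int = DEFAULT_RANK_FLOOR,
    subset_filter: list[str] | None = None,
) -> tuple[ReferenceModel, list[str]]:
    """Fit reference statistics and zero zones for every usable subset.

    All subsets enter the model by default; ``subset_filter`` optionally
    restricts it (e.g. to a significant-subset shortlist).  Subsets with
    too few HC values, a degenerate SD, or no SLE values are skipped with
    a recorded reason.  Returns (model, warnings).
    """
    sle, hc = split_by_group(profiles)
    names = subset_filter if subset_filter is not None else panel_names(profiles)
    subsets: dict[str, SubsetModel] = {}
    skipped: dict[str, str] = {}
    warnings: list[str] = []
    for name in names:
        hc_vals = subset_values(hc, name)
        sle_vals = subset_values(sle, name)
        if len(hc_vals) < MIN_HC_VALUES:
            skipped[name] = f"only {len(hc_vals)} healthy-control values (need {MIN_HC_VALUES})"
        elif not sle_vals:
            skipped[name] = "no SLE values for zero-zone search"
        else:
            stats = fit_reference(hc, name)
            if stats.degenerate:
                skipped[name] = "degenerate reference (SD = 0 after outlier removal)"
            else:
                zone, _ = determine_zero_zone(hc_vals, sle_vals, stats, n_max=n_max)
                subsets[name] = SubsetModel(stats=stats, zone=zone)
                continue
        warnings.append(f"subset {name!r} excluded from the model: {skipped[name]}")
    if not subsets:
        raise DataError("no usable subsets: every subset was skipped")
    model = ReferenceModel(
        subsets=subsets,
        skipped=skipped,
        n_max=n_max,
        band_steps=band_steps,
        rank_floor=rank_floor,
    )
    return model, warnings


def immune_signature(profile: SubjectProfile, model: ReferenceModel) -> SignatureResult:
    """Score one subject: sum of subset ranks over all usable subsets."""
    ranks: dict[str, int] = {}
    skipped = 0
    for name, sm in model.subsets.items():
        v = profile.value(name)
        if v is None:
            skipped += 1
            continue
        ranks[name] = rank_value(
            v, sm.zone, sm.stats, band_steps=model.band_steps,
            rank_floor=model.rank_floor, subject_id=profile.subject_id,
        ).rank
    if not ranks:
        raise DataError(f"subject {profile.subject_id!r}: no usable subsets to score")
    return SignatureResult(
        subject_id=profile.subject_id,
        group=profile.group,
        ranks=ranks,
        score=int(sum(ranks.values())),
        n_subsets_used=len(ranks),
        n_subsets_skipped=skipped,
    )


def score_cohort(
    profiles: list[SubjectProfile], model: ReferenceModel
) -> list[SignatureResult]:
    return [immune_signature(p, model) for p in profiles]
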