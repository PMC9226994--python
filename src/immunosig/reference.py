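"""Healthy-control reference statistics (part 1 of the signature algorithm).

For each immune subset the healthy-control (HC) values define a reference:
first and third quartiles (linear-interpolation convention), Tukey fences
at Q1 - 1.5*IQR and Q3 + 1.5*IQR, one-pass elimination of values strictly
outside the fences (boundary values are retained), and the mean (AVG) and
sample SD of the retained values.  AVG and SD anchor the zero-zone and
ranking stages downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .profiles import SubjectProfile, subset_values

#: quantile convention identifier recorded in serialized models
QUANTILE_CONVENTION = "linear"
MIN_HC_VALUES = 4


def quartiles(values) -> tuple[float, float]:
    """(Q1, Q3) by linear interpolation of order statistics.

    The k-th order statistic sits at probability (k-1)/(n-1); requires at
    least 4 finite values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < MIN_HC_VALUES:
        raise InsufficientDataError(
            f"quartiles need >= {MIN_HC_VALUES} values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InsufficientDataError("quartiles require finite values")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # numpy default = linear interpolation
    return float(q1), float(q3)


def tukey_fences(q1: float, q3: float) -> tuple[float, float]:
    """(lower, upper) = (Q1 - 1.5*IQR, Q3 + 1.5*IQR)."""
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def detect_outliers(values, q1: float, q3: float) -> tuple[list[float], list[float]]:
    """Split values into (retained, outliers) by the Tukey fences.

    A value is an outlier iff it is strictly above the upper fence or
    strictly below the lower fence; values exactly on a fence are retained.
    Input order is preserved in both lists.  One pass only: the fences are
    computed once from the full sample and applied once.
    """
    lower, upper = tukey_fences(q1, q3)
    retained, outliers = [], []
    for v in values:
        v = float(v)
        if v > upper or v < lower:
            outliers.append(v)
        else:
            retained.append(v)
    return retained, outliers


@dataclass
class ReferenceStats:
    """Per-subset reference artifacts fitted from healthy controls."""

    subset: str
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    n_outliers_removed: int
    n_retained: int
    avg: float  # mean of retained HC values
    sd: float  # sample SD (ddof=1) of retained HC values
    degenerate: bool = False  # sd == 0; excluded from scoring

    @property
    def step(self) -> float:
        """One ranking step, SD/10, in percentage points."""
        return self.sd / 10.0


def fit_reference(hc_profiles: list[SubjectProfile], subset: str) -> ReferenceStats:
    """Fit a :class:`ReferenceStats` for one subset from HC profiles.

    Missing values are excluded pairwise; fewer than 4 usable HC values is
    an error naming the subset.
    """
    vals = subset_values(hc_profiles, subset)
    if len(vals) < MIN_HC_VALUES:
        raise InsufficientDataError(
            f"subset {subset!r}: need >= {MIN_HC_VALUES} healthy-control values, "
            f"got {len(vals)}"
        )
    q1, q3 = quartiles(vals)
    retained, outliers = detect_outliers(vals, q1, q3)
    arr = np.asarray(retained, dtype=float)
    avg = float(arr.mean())
    sd = float(arr.std(ddof=1))
    lower, upper = tukey_fences(q1, q3)
    return ReferenceStats(
        subset=subset,
        q1=q1,
        q3=q3,
        iqr=q3 - q1,
        lower_fence=lower,
        upper_fence=upper,
        n_outliers_removed=len(outliers),
        n_retained=len(retained),
        avg=avg,
        sd=sd,
        degenerate=(sd == 0.0 or not math.isfinite(sd)),
    )
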