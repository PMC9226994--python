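"""Two-group differential statistics: the per-subset t-test screen and
demographic-table tests.

The subset screen runs a classical pooled-variance (Student's) unpaired
two-sided t-test per subset, optionally with Holm-Bonferroni adjustment;
no correction is applied unless requested.  Demographics use a two-sided
Fisher exact test for the sex 2x2 table and a two-sample t-test computable
from summary statistics (pooled or Welch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .profiles import SubjectProfile, panel_names, split_by_group, subset_values

ALPHA = 0.05


@dataclass
class SubsetTestResult:
    subset: str
    mean_sle: float
    mean_hc: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    adjusted_p: float | None = None


@dataclass
class DemographicsResult:
    fisher_p: float
    age_t: float
    age_df: float
    age_p: float
    sex_table: tuple[int, int, int, int]  # (female_sle, male_sle, female_hc, male_hc)
    sex_method: str = "Fisher exact, two-sided (probability-mass rule)"
    age_method: str = "two-sample t-test"


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    a, b = s1**2 / n1, s2**2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def subset_ttests(
    profiles: list[SubjectProfile],
    correction: str = "none",
    variant: str = "pooled",
    alpha: float = ALPHA,
) -> tuple[list[SubsetTestResult], list[str]]:
    """Per-subset unpaired two-sided t-tests, sorted by subset name.

    ``correction="holm"`` adds Holm-Bonferroni adjusted p-values and flags
    significance on them; otherwise the raw p < alpha rule is used.
    Subsets with fewer than 2 usable values in either group are skipped
    with a warning.  Returns (results, warnings).
    """
    if correction not in ("none", "holm"):
        raise DataError(f"unknown correction {correction!r}")
    if variant not in ("pooled", "welch"):
        raise DataError(f"unknown t-test variant {variant!r}")
    sle, hc = split_by_group(profiles)
    results: list[SubsetTestResult] = []
    warnings: list[str] = []
    for name in panel_names(profiles):
        xs = subset_values(sle, name)
        xh = subset_values(hc, name)
        if len(xs) < 2 or len(xh) < 2:
            warnings.append(
                f"subset {name!r} skipped: need >= 2 values per group "
                f"(got {len(xs)} SLE / {len(xh)} HC)"
            )
            continue
        equal_var = variant == "pooled"
        t, p = sps.ttest_ind(xs, xh, equal_var=equal_var)
        df = (
            len(xs) + len(xh) - 2
            if equal_var
            else _welch_df(float(np.std(xs, ddof=1)), len(xs), float(np.std(xh, ddof=1)), len(xh))
        )
        results.append(
            SubsetTestResult(
                subset=name,
                mean_sle=float(np.mean(xs)),
                mean_hc=float(np.mean(xh)),
                t_statistic=float(t),
                degrees_of_freedom=float(df),
                p_value=float(p),
                significant=bool(p < alpha),
            )
        )
    if correction == "holm" and results:
        reject, adj, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="holm"
        )
        for r, rej, a in zip(results, reject, adj):
            r.adjusted_p = float(a)
            r.significant = bool(rej)
    return results, warnings


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Uses the probability-mass criterion: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise DataError(f"Fisher exact needs nonnegative integer cells, got {cells}")
    _, p = sps.fisher_exact([[int(a), int(b)], [int(c), int(d)]], alternative="two-sided")
    return float(p)


def ttest_from_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Returns (t, df, p).  Both the pooled-variance and the Welch variant are
    exposed; which one a given published table used is often unrecoverable
    from rounded summaries, so callers can report both side by side.
    """
    if n1 < 2 or n2 < 2:
        raise DataError(f"group sizes must be >= 2, got {n1}, {n2}")
    if not (sd1 > 0 and sd2 > 0):
        raise DataError(f"SDs must be > 0, got {sd1}, {sd2}")
    if variant not in ("pooled", "welch"):
        raise DataError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "pooled"
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    df = n1 + n2 - 2 if equal_var else _welch_df(sd1, n1, sd2, n2)
    return float(t), float(df), float(p)


def compare_demographics(
    profiles: list[SubjectProfile], variant: str = "pooled"
) -> DemographicsResult:
    """Sex (Fisher exact) and age (two-sample t) comparisons for a cohort."""
    sle, hc = split_by_group(profiles)
    f_sle = sum(1 for p in sle if p.sex == "F")
    f_hc = sum(1 for p in hc if p.sex == "F")
    table = (f_sle, len(sle) - f_sle, f_hc, len(hc) - f_hc)
    fisher_p = fisher_exact_2x2(*table)
    ages_sle = [p.age for p in sle if p.age is not None]
    ages_hc = [p.age for p in hc if p.age is not None]
    t, df, p = ttest_from_summary(
        len(ages_sle), float(np.mean(ages_sle)), float(np.std(ages_sle, ddof=1)),
        len(ages_hc), float(np.mean(ages_hc)), float(np.std(ages_hc, ddof=1)),
        variant=variant,
    )
    return DemographicsResult(
        fisher_p=fisher_p,
        age_t=t,
        age_df=df,
        age_p=p,
        sex_table=table,
        age_method=f"two-sample t-test ({variant})",
    )
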