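"""ROC evaluation of immune-signature scores.

Direction convention: SLE is the positive class and *lower* scores are
more SLE-like (signatures are sums of nonpositive ranks), so a subject is
called positive iff score < threshold.  The AUC is the Mann-Whitney
probability P(score_SLE < score_HC) + 0.5 * P(tie).  The operating
threshold maximizes Youden's J = sensitivity + specificity - 1, with ties
broken toward the more negative threshold, and is reported as the midpoint
between the adjacent distinct scores realizing the cutpoint.

The zero zones are fitted with the SLE group in view, so in-sample ROC
figures are optimistic; :func:`loocv_evaluate` audits that optimism by
refitting the whole model without each subject in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, InsufficientDataError
from .profiles import GROUP_SLE, SubjectProfile, split_by_group
from .signature import (
    DEFAULT_BAND_STEPS,
    DEFAULT_N_MAX,
    DEFAULT_RANK_FLOOR,
    fit_signature_model,
    immune_signature,
)

DEFAULT_N_BOOT = 2000


@dataclass
class RocResult:
    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auc: float
    chosen_threshold: float
    sensitivity: float
    specificity: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None


def _as_scores(scores) -> np.ndarray:
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise DataError("score group must be nonempty")
    return arr


def auc_mann_whitney(scores_sle, scores_hc) -> float:
    """AUC as the ordered-pair probability that an SLE score is lower."""
    s = _as_scores(scores_sle)
    h = _as_scores(scores_hc)
    less = (s[:, None] < h[None, :]).sum()
    ties = (s[:, None] == h[None, :]).sum()
    return float((less + 0.5 * ties) / (s.size * h.size))


def _candidate_thresholds(s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """All distinct operating cutpoints: midpoints between adjacent distinct
    scores, plus one below the minimum and one above the maximum."""
    u = np.unique(np.concatenate([s, h]))
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def roc_points(scores_sle, scores_hc) -> list[tuple[float, float, float]]:
    """(threshold, sensitivity, specificity) at every distinct cutpoint,
    ascending in threshold.  Positive call: score < threshold."""
    s = _as_scores(scores_sle)
    h = _as_scores(scores_hc)
    out = []
    for thr in _candidate_thresholds(s, h):
        sens = float(np.mean(s < thr))
        spec = float(np.mean(h >= thr))
        out.append((float(thr), sens, spec))
    return out


def choose_threshold(
    points: list[tuple[float, float, float]],
) -> tuple[float, float, float]:
    """Youden-J maximizer over ROC points; ties go to the more negative
    threshold.  Returns (threshold, sensitivity, specificity)."""
    if not points:
        raise DataError("empty ROC curve")
    best = points[0]
    best_j = best[1] + best[2] - 1.0
    for thr, sens, spec in points[1:]:  # ascending thresholds: first max wins ties
        j = sens + spec - 1.0
        if j > best_j:
            best, best_j = (thr, sens, spec), j
    return best


def bootstrap_ci(
    scores_sle,
    scores_hc,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% CI for the AUC."""
    if n_boot < 200:
        raise DataError(f"n_boot must be >= 200, got {n_boot}")
    s = _as_scores(scores_sle)
    h = _as_scores(scores_hc)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        sb = s[rng.integers(0, s.size, s.size)]
        hb = h[rng.integers(0, h.size, h.size)]
        aucs[b] = auc_mann_whitney(sb, hb)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_scores(
    scores_sle,
    scores_hc,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> RocResult:
    """Full ROC evaluation: curve, AUC, Youden threshold, bootstrap CI."""
    points = roc_points(scores_sle, scores_hc)
    auc = auc_mann_whitney(scores_sle, scores_hc)
    thr, sens, spec = choose_threshold(points)
    ci_low = ci_high = None
    if n_boot:
        ci_low, ci_high = bootstrap_ci(scores_sle, scores_hc, n_boot=n_boot, seed=seed)
    return RocResult(
        points=points,
        auc=auc,
        chosen_threshold=thr,
        sensitivity=sens,
        specificity=spec,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
    )


def loocv_evaluate(
    profiles: list[SubjectProfile],
    n_max: int = DEFAULT_N_MAX,
    band_steps: int = DEFAULT_BAND_STEPS,
    rank_floor: int = DEFAULT_RANK_FLOOR,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[dict[str, int], RocResult]:
    """Leave-one-out audit: refit the model without each subject, score the
    held-out subject, and build the ROC on held-out scores only."""
    sle, hc = split_by_group(profiles)
    if len(sle) < 5 or len(hc) < 5:
        raise InsufficientDataError(
            f"leave-one-out needs >= 5 subjects per group, got {len(sle)} SLE / {len(hc)} HC"
        )
    held: dict[str, int] = {}
    for i, p in enumerate(profiles):
        rest = profiles[:i] + profiles[i + 1 :]
        model, _ = fit_signature_model(
            rest, n_max=n_max, band_steps=band_steps, rank_floor=rank_floor
        )
        held[p.subject_id] = immune_signature(p, model).score
    s_scores = [held[p.subject_id] for p in sle]
    h_scores = [held[p.subject_id] for p in hc]
    return held, evaluate_scores(s_scores, h_scores, n_boot=n_boot, seed=seed)
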