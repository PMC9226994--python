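"""Synthetic cohort generation.

Three fidelity levels:

* :func:`simulate_percentages` — draws each subject's subset percentages
  directly from the group-shift model Normal(mu + delta*sigma*[SLE], sigma)
  truncated to [0, 100], with rare far-tail outliers injected into the
  healthy-control arm to exercise the fence-based outlier handling.
* :func:`simulate_cells` — draws per-subject cell x marker intensity
  matrices from a mixture of phenotyped populations, to be run through the
  gating module.
* :func:`simulate_longitudinal` — monitored-patient trajectories: a
  stochastically declining SLEDAI-2K disease-activity course with subset
  percentages coupled to it (positively for PD-1+ T subsets, negatively
  for PD-L1+ monocytes by default).

Subsets are modelled as independent truncated normals, not a composition
summing to 100: real cytometry subsets are overlapping gates (a PD-1+ CD4
T cell is also a T cell), so no sum constraint applies.

Reproducibility: every value has its own substream derived from
(master seed, subject index, CRC32 of the subset name), so identical
configurations give byte-identical tables and panel edits do not reshuffle
unrelated values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .config import CohortConfig
from .errors import ConfigError, GateDefinitionError
from .gating import CellMatrix, GatingPanel
from .profiles import GROUP_HC, GROUP_SLE, LongitudinalRecord, SubjectProfile

_DEMOGRAPHICS_TAG = 0x00D0_6E0F
_CELLS_TAG = 0x00CE_11AA
_LONG_TAG = 0x0010_DD00


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float,
    max_draws: int = 100,
) -> float:
    """Resample up to ``max_draws`` times into [lo, hi], then clip.

    Keeps the distribution near-normal for mid-range means while remaining
    bounded for means pushed against a boundary.
    """
    v = rng.normal(mean, sd)
    for _ in range(max_draws - 1):
        if lo <= v <= hi:
            return float(v)
        v = rng.normal(mean, sd)
    return float(min(max(v, lo), hi))


def simulate_percentages(config: CohortConfig) -> list[SubjectProfile]:
    """Generate ``n_sle + n_hc`` subject profiles from the group-shift model."""
    config.validate()
    profiles: list[SubjectProfile] = []
    n_total = config.n_sle + config.n_hc
    for i in range(n_total):
        is_sle = i < config.n_sle
        group = GROUP_SLE if is_sle else GROUP_HC
        label = i + 1 if is_sle else i - config.n_sle + 1
        subject_id = f"{group}{label:02d}"

        demo = _rng(config.seed, i, _DEMOGRAPHICS_TAG)
        p_female = config.sex_prob_sle if is_sle else config.sex_prob_hc
        sex = "F" if demo.random() < p_female else "M"
        age_mean = config.age_mean_sle if is_sle else config.age_mean_hc
        age_sd = config.age_sd_sle if is_sle else config.age_sd_hc
        age = _truncated_normal(demo, age_mean, age_sd, config.age_min, config.age_max)

        values: dict[str, float | None] = {}
        for spec in config.panel:
            r = _rng(config.seed, i, _name_key(spec.name))
            mean = spec.mu + (spec.delta * spec.sigma if is_sle else 0.0)
            v = _truncated_normal(r, mean, spec.sigma, 0.0, 100.0)
            if not is_sle and r.random() < config.outlier_rate:
                v = min(spec.mu + 6.0 * spec.sigma, 100.0)
            values[spec.name] = v
        profiles.append(
            SubjectProfile(subject_id=subject_id, group=group, sex=sex, age=age, values=values)
        )
    return profiles


# ---------------------------------------------------------------------------
# cell-level mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellPopulation:
    """A homogeneous cell population: which markers it expresses, and its
    mixture weight per group (fraction of all cells)."""

    name: str
    phenotype: frozenset[str]  # markers expressed "hi"; all others "lo"
    weight_hc: float
    weight_sle: float

    @classmethod
    def of(cls, name: str, markers: str, weight_hc: float, weight_sle: float) -> "CellPopulation":
        return cls(name, frozenset(markers.split()), weight_hc, weight_sle)


def default_cell_populations() -> list[CellPopulation]:
    """A reduced default mixture over the 15-marker panel.

    Weights approximate the percentage-level model's lineage fractions,
    with the SLE arm shifted in the directions of the group effects
    (CD8 T and PD-1+ T up; NK, dendritic cells and PD-L1+ monocytes down).
    """
    P = CellPopulation.of
    pops = [
        P("CD4 T", "CD3 CD4 TCRab", 0.30, 0.28),
        P("CD8 T", "CD3 CD8 TCRab", 0.14, 0.19),
        P("Treg", "CD3 CD4 TCRab CD25 FoxP3", 0.03, 0.03),
        P("PD-1+ CD4 T", "CD3 CD4 TCRab PD-1", 0.03, 0.07),
        P("PD-1+ CD8 T", "CD3 CD8 TCRab PD-1", 0.02, 0.05),
        P("gd T", "CD3 TCRgd", 0.04, 0.04),
        P("B", "CD19 HLA-DR", 0.10, 0.10),
        P("NK", "CD56", 0.12, 0.07),
        P("NKT", "CD3 CD56 TCRab", 0.05, 0.05),
        P("Monocyte", "CD14 CD11c HLA-DR", 0.10, 0.09),
        P("PD-L1+ monocyte", "CD14 CD11c HLA-DR PD-L1", 0.05, 0.02),
        P("DC", "CD11c HLA-DR", 0.015, 0.008),
    ]
    for grp in ("hc", "sle"):
        total = sum(getattr(p, f"weight_{grp}") for p in pops)
        if total > 1.0:
            raise ConfigError(f"cell population weights ({grp}) sum to {total} > 1")
    # remainder: marker-negative "other" events (debris/unclassified)
    pops.append(
        CellPopulation(
            "other", frozenset(),
            1.0 - sum(p.weight_hc for p in pops),
            1.0 - sum(p.weight_sle for p in pops),
        )
    )
    return pops


def simulate_cells(
    config: CohortConfig,
    panel: GatingPanel | None = None,
    populations: list[CellPopulation] | None = None,
    hi_cv: float = 0.18,
    lo_cv: float = 0.45,
) -> dict[str, CellMatrix]:
    """Per-subject cell x marker intensity matrices from a phenotype mixture.

    Expressed markers draw intensities around 3x the positivity threshold,
    unexpressed markers around one third of it, both clipped at zero, so the
    default gates recover each population's mixture weight up to binomial
    sampling error.
    """
    config.validate()
    panel = panel or GatingPanel()
    populations = populations or default_cell_populations()
    marker_set = set(panel.markers)
    for pop in populations:
        bad = pop.phenotype - marker_set
        if bad:
            raise GateDefinitionError(
                f"population {pop.name!r} references markers {sorted(bad)} absent from the panel"
            )

    out: dict[str, CellMatrix] = {}
    n_total = config.n_sle + config.n_hc
    for i in range(n_total):
        is_sle = i < config.n_sle
        group = GROUP_SLE if is_sle else GROUP_HC
        label = i + 1 if is_sle else i - config.n_sle + 1
        subject_id = f"{group}{label:02d}"
        rng = _rng(config.seed, i, _CELLS_TAG)

        weights = np.array(
            [p.weight_sle if is_sle else p.weight_hc for p in populations], dtype=float
        )
        counts = rng.multinomial(config.cells_per_subject, weights / weights.sum())
        blocks = []
        for pop, n in zip(populations, counts):
            if n == 0:
                continue
            means = np.array(
                [
                    3.0 * panel.thresholds[m] if m in pop.phenotype else panel.thresholds[m] / 3.0
                    for m in panel.markers
                ]
            )
            sds = np.array(
                [
                    (hi_cv if m in pop.phenotype else lo_cv) * mu
                    for m, mu in zip(panel.markers, means)
                ]
            )
            blocks.append(np.clip(rng.normal(means, sds, size=(n, len(panel.markers))), 0.0, None))
        cells = np.vstack(blocks)
        rng.shuffle(cells, axis=0)
        out[subject_id] = CellMatrix(subject_id=subject_id, markers=panel.markers, intensities=cells)
    return out


# ---------------------------------------------------------------------------
# longitudinal mode
# ---------------------------------------------------------------------------

#: default coupling of monitored subsets to the disease-activity score
#: (correlation-like strength in [-1, 1]).
DEFAULT_COUPLINGS: dict[str, float] = {
    "PD-1+ CD4 T cells": 0.9,
    "PD-1+ CD8 T cells": 0.9,
    "PD-L1+ monocytes": -0.9,
}

_LONG_BASELINES: dict[str, tuple[float, float]] = {
    # (mean percentage, SD) for monitored subsets
    "PD-1+ CD4 T cells": (8.0, 2.0),
    "PD-1+ CD8 T cells": (6.0, 1.6),
    "PD-L1+ monocytes": (5.0, 1.4),
}


def simulate_longitudinal(
    config: CohortConfig,
    n_patients: int = 4,
    weeks: tuple[int, ...] = (0, 4, 12),
    couplings: dict[str, float] | None = None,
) -> list[LongitudinalRecord]:
    """Monitored-patient records: declining SLEDAI-2K plus coupled subsets.

    Each patient starts at a SLEDAI-2K drawn uniformly from 6..30 (an
    active-disease baseline) which decays stochastically under treatment.
    A subset with coupling c tracks c * standardized(SLEDAI) plus
    sqrt(1 - c^2) independent noise, so c is the model-scale correlation.
    """
    if n_patients < 1:
        raise ConfigError(f"n_patients: must be >= 1, got {n_patients}")
    if not weeks:
        raise ConfigError("weeks: must be nonempty")
    couplings = DEFAULT_COUPLINGS if couplings is None else couplings
    for name, c in couplings.items():
        if not -1.0 <= c <= 1.0:
            raise ConfigError(f"coupling[{name}]: must be in [-1, 1], got {c}")

    records: list[LongitudinalRecord] = []
    for j in range(n_patients):
        rng = _rng(config.seed, j, _LONG_TAG)
        s0 = int(rng.integers(6, 31))
        sledai = [s0]
        for _ in weeks[1:]:
            drop = rng.binomial(sledai[-1], 0.35)  # stochastic response to treatment
            sledai.append(max(0, sledai[-1] - drop))
        arr = np.array(sledai, dtype=float)
        z = (arr - arr.mean()) / arr.std() if arr.std() > 0 else np.zeros_like(arr)

        values_by_week: dict[int, dict[str, float]] = {w: {} for w in weeks}
        for name, c in couplings.items():
            mu, sigma = _LONG_BASELINES.get(name, (5.0, 1.5))
            noise = rng.normal(0.0, 1.0, size=len(weeks))
            pct = mu + sigma * (c * z + np.sqrt(max(0.0, 1.0 - c * c)) * noise)
            for w, v in zip(weeks, np.clip(pct, 0.0, 100.0)):
                values_by_week[w][name] = float(v)

        leu = np.clip(rng.normal(7.0, 2.5, size=len(weeks)), 2.0, 20.0)
        for k, w in enumerate(weeks):
            records.append(
                LongitudinalRecord(
                    patient_id=f"P{j + 1:02d}",
                    week=int(w),
                    sledai2k=int(sledai[k]),
                    leucocyte_count=float(round(leu[k], 1)),
                    values=values_by_week[w],
                )
            )
    return records
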