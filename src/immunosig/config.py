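"""Cohort configuration and the default synthetic study design.

The default configuration mirrors the structure of the published study this
package emulates: 13 newly diagnosed SLE patients vs 9 healthy controls
(HC), a panel of 93 immune-cell subsets of which 29 carry a group effect,
female fractions of 12/13 and 8/9, and ages drawn from Normal(45.9, 10.7)
and Normal(38.3, 14.5) years truncated to the eligibility window [20, 65].

The 93 subset names below are a synthetic reconstruction: the study's gate
list was never published, so these names are plausible PBMC subsets (lineage
populations plus PD-1+, PD-L1+ and MHC II+ overlays) and must not be read
as the original gate definitions.  Affected-subset direction signs follow
the reported findings: dendritic cells, NK cells and PD-L1+ subsets are
lowered in SLE; CD8 T, PD-1+ and MHC II+ subsets (except MHC II+ dendritic
cells) are raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError

DEFAULT_EFFECT_SIZE = 3.5  # |delta| in HC standard deviations
DEFAULT_SEED = 42

# (name, HC mean percentage, effect-direction sign: +1 raised in SLE,
#  -1 lowered in SLE, 0 unaffected).  93 entries, 29 with nonzero sign.
_DEFAULT_PANEL_TABLE: tuple[tuple[str, float, int], ...] = (
    # -- lineage, T-cell and regulatory populations ---------------------
    ("T cells", 62.0, 0),
    ("alpha-beta T cells", 55.0, 0),
    ("gamma-delta T cells", 4.0, 0),
    ("CD4 T cells", 36.0, 0),
    ("CD8 T cells", 22.0, +1),
    ("Naive CD4 T cells", 18.0, 0),
    ("Naive CD8 T cells", 8.0, +1),
    ("Effector CD4 T cells", 10.0, 0),
    ("Effector CD8 T cells", 7.0, 0),
    ("Memory CD4 T cells", 12.0, 0),
    ("Memory CD8 T cells", 6.0, 0),
    ("Central memory CD4 T cells", 7.0, 0),
    ("Effector memory CD4 T cells", 5.0, 0),
    ("Central memory CD8 T cells", 3.0, 0),
    ("Effector memory CD8 T cells", 3.5, 0),
    ("Double-negative T cells", 3.0, 0),
    ("Double-positive T cells", 1.0, 0),
    ("CD25+ CD4 T cells", 6.0, 0),
    ("CD25+ CD8 T cells", 2.5, -1),
    ("Activated CD4 T cells", 3.0, 0),
    ("Activated CD8 T cells", 2.5, 0),
    ("Regulatory T cells", 3.0, 0),
    ("CD8 regulatory T cells", 1.2, 0),
    ("FoxP3+ CD8 T cells", 0.9, 0),
    ("CTLA-4+ CD4 T cells", 2.0, 0),
    ("CTLA-4+ CD8 T cells", 1.3, 0),
    ("CTLA-4+ regulatory T cells", 1.0, 0),
    ("gamma-delta CD8 T cells", 1.5, 0),
    ("B cells", 10.0, 0),
    ("Naive B cells", 6.0, 0),
    ("Memory B cells", 3.0, 0),
    ("Transitional B cells", 1.0, 0),
    ("Plasmablasts", 0.7, 0),
    ("NK cells", 12.0, -1),
    ("CD56-bright NK cells", 1.5, 0),
    ("CD56-dim NK cells", 10.0, 0),
    ("CD25+ NK cells", 1.1, 0),
    ("CD69+ NK cells", 1.5, 0),
    ("NKT cells", 5.0, 0),
    ("CD4 NKT cells", 1.5, 0),
    ("CD8 NKT cells", 2.5, +1),
    ("CD8 regulatory NKT cells", 0.8, +1),
    ("CD69+ NKT cells", 0.9, 0),
    ("Monocytes", 15.0, 0),
    ("Classical monocytes", 12.0, 0),
    ("Intermediate monocytes", 2.5, 0),
    ("Non-classical monocytes", 2.0, 0),
    ("CD11c+ monocytes", 8.0, 0),
    ("Dendritic cells", 2.0, -1),
    ("Myeloid dendritic cells", 1.2, 0),
    ("Plasmacytoid dendritic cells", 0.6, 0),
    # -- PD-1+ (checkpoint-receptor) overlays ---------------------------
    ("PD-1+ T cells", 8.0, 0),
    ("PD-1+ alpha-beta T cells", 7.5, +1),
    ("PD-1+ gamma-delta T cells", 1.0, 0),
    ("PD-1+ CD4 T cells", 5.0, +1),
    ("PD-1+ CD8 T cells", 4.0, +1),
    ("PD-1+ naive CD4 T cells", 2.5, +1),
    ("PD-1+ naive CD8 T cells", 1.5, 0),
    ("PD-1+ effector CD4 T cells", 2.0, 0),
    ("PD-1+ effector CD8 T cells", 1.8, +1),
    ("PD-1+ CD25+ CD4 T cells", 1.2, +1),
    ("PD-1+ activated CD8 T cells", 1.0, +1),
    ("PD-1+ NK cells", 1.5, 0),
    ("PD-1+ NKT cells", 1.2, 0),
    ("PD-1+ monocytes", 1.0, 0),
    # -- PD-L1+ (checkpoint-ligand) overlays ----------------------------
    ("PD-L1+ PBMCs", 18.0, -1),
    ("PD-L1+ T cells", 6.0, -1),
    ("PD-L1+ alpha-beta T cells", 5.5, 0),
    ("PD-L1+ gamma-delta T cells", 0.8, 0),
    ("PD-L1+ CD4 T cells", 3.5, -1),
    ("PD-L1+ CD8 T cells", 2.5, -1),
    ("PD-L1+ naive CD4 T cells", 1.5, 0),
    ("PD-L1+ B cells", 2.0, 0),
    ("PD-L1+ NK cells", 4.0, -1),
    ("PD-L1+ NKT cells", 2.2, -1),
    ("PD-L1+ CD8 NKT cells", 1.1, -1),
    ("PD-L1+ CD4 NKT cells", 0.8, 0),
    ("PD-L1+ monocytes", 7.0, -1),
    ("PD-L1+ dendritic cells", 1.0, 0),
    # -- MHC II+ (HLA-DR, antigen-presentation) overlays ----------------
    ("MHC II+ PBMCs", 30.0, 0),
    ("MHC II+ T cells", 6.0, +1),
    ("MHC II+ alpha-beta T cells", 5.5, 0),
    ("MHC II+ gamma-delta T cells", 0.9, 0),
    ("MHC II+ CD4 T cells", 3.5, +1),
    ("MHC II+ CD8 T cells", 2.8, +1),
    ("MHC II+ B cells", 9.5, 0),
    ("MHC II+ NK cells", 1.8, +1),
    ("MHC II+ NKT cells", 1.4, +1),
    ("MHC II+ CD8 NKT cells", 0.9, 0),
    ("MHC II+ CD4 NKT cells", 0.6, 0),
    ("MHC II+ regulatory T cells", 1.1, 0),
    ("MHC II+ monocytes", 13.0, +1),
    ("MHC II+ dendritic cells", 1.8, -1),
)


@dataclass(frozen=True)
class SubsetSpec:
    """Generative parameters of one immune subset.

    ``mu``/``sigma`` are the healthy-control mean and SD in percentage
    points; ``delta`` is the SLE shift in units of ``sigma`` (signed, 0 for
    unaffected subsets); ``parent`` optionally names the enclosing subset
    (used only for gating-consistency checks).
    """

    name: str
    mu: float
    sigma: float
    delta: float = 0.0
    parent: str | None = None

    def validate(self) -> None:
        if not self.name:
            raise ConfigError("panel: subset name must be non-empty")
        if not 0.0 <= self.mu <= 100.0:
            raise ConfigError(f"panel[{self.name}].mu: must be in [0, 100], got {self.mu}")
        if not self.sigma > 0:
            raise ConfigError(f"panel[{self.name}].sigma: must be > 0, got {self.sigma}")
        import math

        if not math.isfinite(self.delta):
            raise ConfigError(f"panel[{self.name}].delta: must be finite")


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_sle: int = 13
    n_hc: int = 9
    panel: list[SubsetSpec] = field(default_factory=list)
    seed: int = DEFAULT_SEED
    sex_prob_sle: float = 12 / 13  # probability of female
    sex_prob_hc: float = 8 / 9
    age_mean_sle: float = 45.9
    age_sd_sle: float = 10.7
    age_mean_hc: float = 38.3
    age_sd_hc: float = 14.5
    age_min: float = 20.0
    age_max: float = 65.0
    # chance an HC value is replaced by the far-tail value mu + 6 sigma.
    # Default 0: the baseline study conditions are the clean group-shift
    # model; even rare 6-sigma contamination of 9 controls inflates the
    # pooled variance enough to mask genuine 3.5 SD shifts, which is a
    # robustness scenario, not the baseline.  Raise it to exercise the
    # fence-based outlier handling.
    outlier_rate: float = 0.0
    cells_per_subject: int = 5000  # cell-level mode only

    def validate(self) -> None:
        if self.n_sle < 2:
            raise ConfigError(f"n_sle: must be >= 2, got {self.n_sle}")
        if self.n_hc < 4:
            raise ConfigError(f"n_hc: must be >= 4 (quartiles need >= 4 points), got {self.n_hc}")
        if not self.panel:
            raise ConfigError("panel: must contain at least one subset")
        names = [s.name for s in self.panel]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"panel: duplicate subset names {dup}")
        for s in self.panel:
            s.validate()
        for probf in ("sex_prob_sle", "sex_prob_hc", "outlier_rate"):
            v = getattr(self, probf)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{probf}: must be in [0, 1], got {v}")
        for sdf in ("age_sd_sle", "age_sd_hc"):
            if not getattr(self, sdf) > 0:
                raise ConfigError(f"{sdf}: must be > 0, got {getattr(self, sdf)}")
        if self.age_min >= self.age_max:
            raise ConfigError("age_min: must be < age_max")
        if self.cells_per_subject < 100:
            raise ConfigError(
                f"cells_per_subject: must be >= 100, got {self.cells_per_subject}"
            )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = [asdict(s) for s in self.panel]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        if not isinstance(d, dict):
            raise ConfigError("config: expected a mapping at top level")
        d = dict(d)
        panel_raw = d.pop("panel", [])
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"config: unknown fields {sorted(unknown)}")
        try:
            panel = [SubsetSpec(**entry) for entry in panel_raw]
        except TypeError as exc:
            raise ConfigError(f"panel: malformed subset entry ({exc})") from exc
        return cls(panel=panel, **d)


def default_sigma(mu: float) -> float:
    """Default HC standard deviation: 20% of the mean, floored at 0.3 points."""
    return max(0.3, 0.2 * mu)


def default_study_config(
    seed: int = DEFAULT_SEED, effect_size: float = DEFAULT_EFFECT_SIZE
) -> CohortConfig:
    """The default synthetic study: 13 SLE vs 9 HC over 93 subsets, 29 affected.

    ``effect_size`` is the absolute SLE shift of affected subsets in HC
    standard deviations (default 3.5).
    """
    panel = [
        SubsetSpec(name=name, mu=mu, sigma=default_sigma(mu), delta=sign * effect_size)
        for name, mu, sign in _DEFAULT_PANEL_TABLE
    ]
    cfg = CohortConfig(panel=panel, seed=seed)
    cfg.validate()
    return cfg


def load_config(path) -> CohortConfig:
    """Read a cohort configuration from a YAML file, with validation."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config file {path}: not valid YAML ({exc})") from exc
    cfg = CohortConfig.from_dict(raw)
    cfg.validate()
    return cfg


def dump_config(config: CohortConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
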