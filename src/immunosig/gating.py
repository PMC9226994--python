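"""Boolean-predicate gating of single-cell marker matrices.

A gate is a conjunction of per-marker sign requirements (e.g. CD3+ CD56-)
optionally nested under a parent gate, mimicking the sequential gating a
cytometrist performs.  Positivity is strict: a cell is positive for a
marker iff its intensity is strictly greater than the panel threshold
(ties count as negative).  Subset content is reported as a percentage of
the parent population, or of all cells when the gate has no parent; an
empty denominator yields a missing value (never zero) plus a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, GateDefinitionError

#: 15 markers in the default staining panel.
DEFAULT_MARKERS: tuple[str, ...] = (
    "CD3", "CD4", "CD8", "CD14", "CD19", "CD56", "CD11c", "HLA-DR",
    "TCRab", "TCRgd", "CD25", "CD69", "FoxP3", "PD-1", "PD-L1",
)
DEFAULT_THRESHOLD = 300.0  # arbitrary fluorescence-intensity units


@dataclass
class GatingPanel:
    markers: tuple[str, ...] = DEFAULT_MARKERS
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        if len(set(self.markers)) != len(self.markers):
            raise GateDefinitionError("panel markers must be unique")
        if not self.thresholds:
            self.thresholds = {m: DEFAULT_THRESHOLD for m in self.markers}
        missing = set(self.markers) - set(self.thresholds)
        if missing:
            raise GateDefinitionError(f"no threshold for markers {sorted(missing)}")
        for m, t in self.thresholds.items():
            if not np.isfinite(t):
                raise GateDefinitionError(f"threshold for {m!r} must be finite")

    def column(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise GateDefinitionError(f"unknown marker {marker!r}") from None


@dataclass
class GateDefinition:
    """A named conjunction of (marker, positive?) clauses under an optional parent."""

    name: str
    clauses: list[tuple[str, bool]]
    parent: str | None = None

    @classmethod
    def parse(cls, name: str, clause_strs: list[str], parent: str | None = None) -> "GateDefinition":
        """Build from clause strings like ``"CD3+"`` / ``"CD56-"``."""
        clauses = []
        for s in clause_strs:
            s = s.strip()
            if len(s) < 2 or s[-1] not in "+-−":
                raise GateDefinitionError(f"gate {name!r}: malformed clause {s!r}")
            clauses.append((s[:-1], s[-1] == "+"))
        return cls(name=name, clauses=clauses, parent=parent)


@dataclass
class CellMatrix:
    """One subject's cells x markers intensity matrix (nonnegative)."""

    subject_id: str
    markers: tuple[str, ...]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[0] < 1:
            raise DataError(f"cell matrix {self.subject_id}: need >= 1 cell")
        if self.intensities.shape[1] != len(self.markers):
            raise DataError(
                f"cell matrix {self.subject_id}: {self.intensities.shape[1]} columns "
                f"for {len(self.markers)} markers"
            )


def _resolve_chain(
    gate: GateDefinition, index: dict[str, GateDefinition]
) -> list[GateDefinition]:
    """Gate plus all ancestors, child first; raises on unknown/cyclic parents."""
    chain = [gate]
    seen = {gate.name}
    g = gate
    while g.parent is not None:
        if g.parent not in index:
            raise GateDefinitionError(f"gate {g.name!r}: unknown parent {g.parent!r}")
        g = index[g.parent]
        if g.name in seen:
            raise GateDefinitionError(f"gate {gate.name!r}: cyclic parent chain at {g.name!r}")
        seen.add(g.name)
        chain.append(g)
    return chain


def _clause_mask(cells: CellMatrix, panel: GatingPanel, gate: GateDefinition) -> np.ndarray:
    mask = np.ones(cells.intensities.shape[0], dtype=bool)
    for marker, positive in gate.clauses:
        col = panel.column(marker)
        pos = cells.intensities[:, col] > panel.thresholds[marker]
        mask &= pos if positive else ~pos
    return mask


def evaluate_gate(
    cells: CellMatrix,
    panel: GatingPanel,
    gate: GateDefinition,
    gate_index: dict[str, GateDefinition] | None = None,
) -> np.ndarray:
    """Boolean membership mask: every clause satisfied and inside the parent gate."""
    index = gate_index or {gate.name: gate}
    mask = np.ones(cells.intensities.shape[0], dtype=bool)
    for g in _resolve_chain(gate, index):
        mask &= _clause_mask(cells, panel, g)
    return mask


def subset_percentages(
    cells: CellMatrix,
    panel: GatingPanel,
    gates: list[GateDefinition],
) -> tuple[dict[str, float | None], list[str]]:
    """Percentages per gate: 100 x members / parent-population size.

    The denominator is the parent gate population, or all cells for a
    root gate.  An empty denominator produces ``None`` and a warning
    string; it is never reported as zero.
    """
    index = {g.name: g for g in gates}
    if len(index) != len(gates):
        raise GateDefinitionError("gate names must be unique")
    masks = {g.name: evaluate_gate(cells, panel, g, index) for g in gates}
    n_cells = cells.intensities.shape[0]
    out: dict[str, float | None] = {}
    warnings: list[str] = []
    for g in gates:
        denom = int(masks[g.parent].sum()) if g.parent is not None else n_cells
        if denom == 0:
            out[g.name] = None
            warnings.append(
                f"subject {cells.subject_id}: gate {g.name!r} has empty parent "
                f"{g.parent!r}; percentage recorded as missing"
            )
            continue
        out[g.name] = 100.0 * int(masks[g.name].sum()) / denom
    return out, warnings


def default_gates() -> list[GateDefinition]:
    """A small default gating tree over the 15-marker panel."""
    P = GateDefinition.parse
    return [
        P("T cells", ["CD3+"]),
        P("CD4 T cells", ["CD4+"], parent="T cells"),
        P("CD8 T cells", ["CD8+"], parent="T cells"),
        P("B cells", ["CD19+"]),
        P("NK cells", ["CD3-", "CD56+"]),
        P("NKT cells", ["CD3+", "CD56+"]),
        P("Monocytes", ["CD14+"]),
        P("Dendritic cells", ["CD3-", "CD19-", "CD56-", "CD14-", "CD11c+", "HLA-DR+"]),
        P("Regulatory T cells", ["CD25+", "FoxP3+"], parent="CD4 T cells"),
        P("PD-1+ CD4 T cells", ["PD-1+"], parent="CD4 T cells"),
        P("PD-1+ CD8 T cells", ["PD-1+"], parent="CD8 T cells"),
        P("PD-L1+ monocytes", ["PD-L1+"], parent="Monocytes"),
    ]
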