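import numpy as np
import pytest

from conftest import make_small_config
from immunosig import io
from immunosig.config import CohortConfig, SubsetSpec, default_study_config
from immunosig.diffstats import subset_ttests
from immunosig.errors import ConfigError
from immunosig.gating import GatingPanel, default_gates, subset_percentages
from immunosig.simulate import (
    CellPopulation,
    default_cell_populations,
    simulate_cells,
    simulate_longitudinal,
    simulate_percentages,
)


class TestSimulatePercentages:
    def test_cohort_shape_and_ranges(self, study_cohort):
        assert len(study_cohort) == 22
        assert sum(p.group == "SLE" for p in study_cohort) == 13
        for p in study_cohort:
            assert len(p.values) == 93
            assert all(0.0 <= v <= 100.0 for v in p.values.values())
            assert 20.0 <= p.age <= 65.0
            assert p.sex in ("F", "M")

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = make_small_config(seed=3)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        io.write_subject_table(simulate_percentages(cfg), a)
        io.write_subject_table(simulate_percentages(cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_percentages(make_small_config(seed=1))
        b = simulate_percentages(make_small_config(seed=2))
        assert a[0].values != b[0].values

    def test_panel_edit_does_not_reshuffle_other_subsets(self):
        cfg = make_small_config(seed=5)
        full = simulate_percentages(cfg)
        trimmed_cfg = make_small_config(seed=5)
        trimmed_cfg.panel = trimmed_cfg.panel[:-1]  # drop one subset
        trimmed = simulate_percentages(trimmed_cfg)
        kept = [s.name for s in trimmed_cfg.panel]
        for pf, pt in zip(full, trimmed):
            assert {k: pf.values[k] for k in kept} == pt.values

    def test_null_effect_tiny_sigma_collapses_to_mu(self):
        panel = [SubsetSpec("x", 40.0, 1e-6, delta=0.0)]
        cfg = CohortConfig(n_sle=4, n_hc=4, panel=panel, seed=0)
        for p in simulate_percentages(cfg):
            assert p.values["x"] == pytest.approx(40.0, abs=1e-4)

    def test_group_shift_applied_to_sle_only(self):
        cfg = make_small_config(seed=9, n_sle=40, n_hc=40, n_subsets=2,
                                effect=3.0, n_affected=1)
        profiles = simulate_percentages(cfg)
        spec = cfg.panel[0]
        sle = [p.values[spec.name] for p in profiles if p.group == "SLE"]
        hc = [p.values[spec.name] for p in profiles if p.group == "HC"]
        assert np.mean(sle) - np.mean(hc) == pytest.approx(3.0 * spec.sigma, abs=spec.sigma)

    def test_outlier_injection_hits_hc_only(self):
        cfg = make_small_config(seed=11, n_sle=20, n_hc=20, n_subsets=6, outlier_rate=0.5)
        profiles = simulate_percentages(cfg)
        n_out = 0
        for p in profiles:
            for s in cfg.panel:
                if p.values[s.name] == pytest.approx(s.mu + 6 * s.sigma):
                    assert p.group == "HC"
                    n_out += 1
        assert n_out > 20  # ~half of the 120 HC values

    def test_invalid_config_rejected_before_generation(self):
        cfg = make_small_config()
        cfg.n_hc = 2
        with pytest.raises(ConfigError, match="n_hc"):
            simulate_percentages(cfg)


class TestSimulateCells:
    def test_degenerate_single_population_gates_to_100(self):
        cfg = make_small_config(n_sle=2, n_hc=4)
        cfg.cells_per_subject = 500
        pops = [CellPopulation.of("T", "CD3 CD4 TCRab", 1.0, 1.0)]
        panel = GatingPanel()
        cells = simulate_cells(cfg, panel, populations=pops)
        gates = [g for g in default_gates() if g.name == "T cells"]
        for cm in cells.values():
            values, _ = subset_percentages(cm, panel, gates)
            assert values["T cells"] == pytest.approx(100.0, abs=0.5)

    def test_two_equal_populations_split_evenly(self):
        cfg = make_small_config(n_sle=2, n_hc=4)
        cfg.cells_per_subject = 4000
        pops = [
            CellPopulation.of("T", "CD3", 0.5, 0.5),
            CellPopulation.of("notT", "CD19", 0.5, 0.5),
        ]
        panel = GatingPanel()
        cells = simulate_cells(cfg, panel, populations=pops)
        gates = [g for g in default_gates() if g.name == "T cells"]
        se = 100 * np.sqrt(0.25 / cfg.cells_per_subject)
        for cm in cells.values():
            values, _ = subset_percentages(cm, panel, gates)
            assert values["T cells"] == pytest.approx(50.0, abs=4 * se)

    def test_default_mixture_recovers_weights_within_3se(self):
        cfg = make_small_config(n_sle=2, n_hc=4, seed=21)
        cfg.cells_per_subject = 10_000
        panel = GatingPanel()
        pops = default_cell_populations()
        cells = simulate_cells(cfg, panel)
        gates = [g for g in default_gates() if g.name in ("B cells", "Monocytes", "NK cells")]
        expected_hc = {
            "B cells": sum(p.weight_hc for p in pops if "CD19" in p.phenotype),
            "Monocytes": sum(p.weight_hc for p in pops if "CD14" in p.phenotype),
            "NK cells": sum(
                p.weight_hc for p in pops if "CD56" in p.phenotype and "CD3" not in p.phenotype
            ),
        }
        hc_matrices = [cm for sid, cm in cells.items() if sid.startswith("HC")]
        for cm in hc_matrices:
            values, _ = subset_percentages(cm, panel, gates)
            for name, frac in expected_hc.items():
                se = 100 * np.sqrt(frac * (1 - frac) / cfg.cells_per_subject)
                assert values[name] == pytest.approx(100 * frac, abs=3 * se), name

    def test_unknown_phenotype_marker_rejected(self):
        from immunosig.errors import GateDefinitionError

        cfg = make_small_config(n_sle=2, n_hc=4)
        cfg.cells_per_subject = 200
        pops = [CellPopulation.of("bad", "CD99", 1.0, 1.0)]
        with pytest.raises(GateDefinitionError, match="CD99"):
            simulate_cells(cfg, GatingPanel(), populations=pops)


class TestSimulateLongitudinal:
    def test_record_layout(self):
        cfg = make_small_config(seed=2)
        records = simulate_longitudinal(cfg, n_patients=4, weeks=(0, 4, 12))
        assert len(records) == 12
        weeks = {(r.patient_id, r.week) for r in records}
        assert len(weeks) == 12  # unique weeks per patient
        for r in records:
            assert r.sledai2k >= 0
            assert set(r.values) == {
                "PD-1+ CD4 T cells", "PD-1+ CD8 T cells", "PD-L1+ monocytes"
            }

    def test_null_coupling_centres_correlations_on_zero(self):
        from immunosig.longitudinal import compute_associations

        cfg = make_small_config(seed=13)
        records = simulate_longitudinal(
            cfg, n_patients=200, weeks=(0, 4, 12), couplings={"marker": 0.0}
        )
        assoc, _ = compute_associations(records, subsets=["marker"])
        rhos = [a.rho for a in assoc if not np.isnan(a.rho)]
        assert len(rhos) > 100
        assert abs(np.mean(rhos)) < 0.2

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ConfigError, match="coupling"):
            simulate_longitudinal(make_small_config(), couplings={"x": 2.0})

    def test_empty_weeks_rejected(self):
        with pytest.raises(ConfigError, match="weeks"):
            simulate_longitudinal(make_small_config(), weeks=())
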