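import numpy as np
import pytest

from _oracles import rank_direct, zero_zone_scan
from conftest import make_small_config
from immunosig.errors import DataError
from immunosig.profiles import SubjectProfile, split_by_group
from immunosig.reference import ReferenceStats
from immunosig.signature import (
    ZeroZone,
    cover_ratio,
    determine_zero_zone,
    fit_signature_model,
    immune_signature,
    rank_value,
    score_cohort,
)
from immunosig.simulate import simulate_percentages


def stats(avg, sd, subset="x"):
    return ReferenceStats(
        subset=subset, q1=0, q3=0, iqr=0, lower_fence=0, upper_fence=0,
        n_outliers_removed=0, n_retained=0, avg=avg, sd=sd,
    )


class TestCoverRatio:
    def test_point_at_centre(self):
        assert cover_ratio([10], 10, 3.0, 0) == 1.0

    def test_hand_counts_around_zone_boundary(self):
        assert cover_ratio([9, 10, 11], 10, 1.0, 9) == pytest.approx(1 / 3)
        assert cover_ratio([9, 10, 11], 10, 1.0, 10) == 1.0  # bounds inclusive

    def test_saturation(self):
        vals = [1, 50, 99]
        assert cover_ratio(vals, 50, 10.0, 50) == 1.0

    def test_empty_list_is_error(self):
        with pytest.raises(DataError):
            cover_ratio([], 10, 1, 1)


class TestDetermineZeroZone:
    def test_hand_enumerated_example(self):
        zone, curve = determine_zero_zone([9, 10, 11], [5, 6, 7], stats(10, 1.0))
        assert zone.n_star == 10
        assert (zone.lower, zone.upper) == (9.0, 11.0)
        assert curve.diff[10] == 1.0

    def test_identical_groups_give_degenerate_zone(self):
        vals = [8, 9, 10, 11, 12]
        zone, curve = determine_zero_zone(vals, vals, stats(10, 1.0))
        assert zone.n_star == 0
        assert zone.lower == zone.upper == 10.0
        assert np.all(curve.diff == 0.0)

    def test_cover_curves_nondecreasing(self):
        rng = np.random.default_rng(4)
        zone, curve = determine_zero_zone(
            rng.normal(20, 3, 9), rng.normal(12, 3, 13), stats(20, 3.0)
        )
        assert np.all(np.diff(curve.cover_hc) >= 0)
        assert np.all(np.diff(curve.cover_sle) >= 0)
        assert np.all(np.abs(curve.diff) <= 1)

    def test_argmax_matches_bruteforce_scan_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(250):
            avg = rng.uniform(5, 50)
            sd = rng.uniform(0.2, 8)
            hc = rng.normal(avg, sd, rng.integers(2, 11)).tolist()
            sle = rng.normal(avg + rng.uniform(-4, 4) * sd, sd, rng.integers(2, 11)).tolist()
            zone, _ = determine_zero_zone(hc, sle, stats(avg, sd), n_max=40)
            assert zone.n_star == zero_zone_scan(hc, sle, avg, sd, 40)

    def test_degenerate_sd_rejected(self):
        s = stats(10, 0.0)
        s.degenerate = True
        with pytest.raises(DataError, match="degenerate"):
            determine_zero_zone([1, 2], [3, 4], s)


class TestRankValue:
    def test_centre_of_zone_is_rank_zero(self):
        zone = ZeroZone("x", 10, 9.0, 11.0)
        assert rank_value(10.0, zone, stats(10, 1.0)).rank == 0

    def test_hand_arithmetic_bands(self):
        zone = ZeroZone("x", 10, 9.0, 11.0)
        r2 = rank_value(7.0, zone, stats(10, 1.0))
        assert (r2.deviation_steps, r2.rank) == (20, -2)
        r3 = rank_value(6.0, zone, stats(10, 1.0))
        assert (r3.deviation_steps, r3.rank) == (30, -3)

    def test_minimal_deviation_is_band_one(self):
        zone = ZeroZone("x", 10, 9.0, 11.0)
        r = rank_value(11.01, zone, stats(10, 1.0))
        assert (r.deviation_steps, r.rank) == (1, -1)

    def test_boundary_takes_less_negative_rank(self):
        zone = ZeroZone("x", 10, 9.0, 11.0)
        assert rank_value(11.0, zone, stats(10, 1.0)).rank == 0  # on zone edge
        assert rank_value(12.0, zone, stats(10, 1.0)).rank == -1  # exactly 1 SD out
        assert rank_value(13.0, zone, stats(10, 1.0)).rank == -2  # exactly 2 SD out

    def test_matches_bruteforce_band_scan_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(250):
            avg = rng.uniform(5, 50)
            sd = rng.uniform(0.2, 8)
            n_star = int(rng.integers(0, 30))
            zone = ZeroZone("x", n_star, avg - n_star * sd / 10, avg + n_star * sd / 10)
            v = rng.uniform(0, 100)
            assert rank_value(v, zone, stats(avg, sd)).rank == rank_direct(
                v, zone.lower, zone.upper, sd
            )

    def test_monotone_deviation_never_increases_rank(self):
        zone = ZeroZone("x", 10, 9.0, 11.0)
        ranks = [rank_value(11.0 + d, zone, stats(10, 1.0)).rank for d in np.linspace(0, 5, 200)]
        assert all(b <= a for a, b in zip(ranks, ranks[1:]))


class TestImmuneSignature:
    def test_reference_typical_subject_scores_zero(self):
        cfg = make_small_config(seed=1, n_subsets=5)
        profiles = simulate_percentages(cfg)
        model, _ = fit_signature_model(profiles)
        typical = SubjectProfile(
            "new", "HC", values={n: sm.stats.avg for n, sm in model.subsets.items()}
        )
        assert immune_signature(typical, model).score == 0

    def test_singleton_model_sum(self):
        cfg = make_small_config(seed=2, n_subsets=1)
        profiles = simulate_percentages(cfg)
        model, _ = fit_signature_model(profiles)
        (sm,) = model.subsets.values()
        v = sm.zone.upper + 1.5 * sm.stats.sd  # 15 steps out -> band 2
        subject = SubjectProfile("s", "SLE", values={sm.stats.subset: min(v, 100.0)})
        assert immune_signature(subject, model).score == -2

    def test_missing_values_counted_skipped(self):
        cfg = make_small_config(seed=3, n_subsets=4)
        profiles = simulate_percentages(cfg)
        model, _ = fit_signature_model(profiles)
        partial = SubjectProfile("s", "HC", values={cfg.panel[0].name: 10.0})
        res = immune_signature(partial, model)
        assert res.n_subsets_used == 1
        assert res.n_subsets_skipped == 3

    def test_no_usable_subsets_is_error(self, study_model):
        empty = SubjectProfile("s", "HC", values={})
        with pytest.raises(DataError, match="no usable subsets"):
            immune_signature(empty, study_model)

    def test_score_bounds_and_integrality(self, study_scores):
        for r in study_scores:
            assert isinstance(r.score, int)
            assert -3 * r.n_subsets_used <= r.score <= 0
            assert r.score == sum(r.ranks.values())
            assert set(r.ranks.values()) <= {0, -1, -2, -3}

    def test_default_cohort_separates_groups_completely(self, study_scores):
        sle = [r.score for r in study_scores if r.group == "SLE"]
        hc = [r.score for r in study_scores if r.group == "HC"]
        assert max(sle) < min(hc)

    def test_affine_invariance_of_signatures(self):
        # scaling one subset's values for every subject leaves all ranks alone
        cfg = make_small_config(seed=7, n_subsets=6, effect=2.0, n_affected=2)
        profiles = simulate_percentages(cfg)
        base = [r.score for r in score_cohort(profiles, fit_signature_model(profiles)[0])]
        a, b = 2.5, 7.0
        target = cfg.panel[0].name
        for p in profiles:
            p.values[target] = a * p.values[target] + b
        scaled = [r.score for r in score_cohort(profiles, fit_signature_model(profiles)[0])]
        assert scaled == base

    def test_degenerate_subset_excluded_with_warning(self):
        cfg = make_small_config(seed=8, n_subsets=3)
        profiles = simulate_percentages(cfg)
        for p in profiles:
            p.values["flat"] = 5.0  # constant in both groups
        model, warnings = fit_signature_model(profiles)
        assert "flat" not in model.subsets
        assert "flat" in model.skipped
        assert any("flat" in w for w in warnings)
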