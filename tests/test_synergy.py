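"""Log-rank scans, synergy scoring, and quadrant enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import STRONG_INTERACTION
from hupred.selection import derive_features, label_cohort, survival_from_labels
from hupred.simulate import GeneratorConfig, generate_cohort
from hupred.synergy import (
    GridRule,
    NoValidSplitError,
    SurvivalData,
    best_pair_split,
    best_single_split,
    compute_pair_synergy,
    logrank_scan,
    logrank_test,
    quadrant_enrichment,
    rank_pairs,
    synergy_score,
)


def _random_survival(rng, n):
    return SurvivalData(
        time=rng.integers(5, 300, size=n).astype(float), event=rng.random(n) < 0.6
    )


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = np.array([5.0, 10.0, 15.0, 20.0])
        e = np.array([True, True, False, True])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.integers(1, 50, 20).astype(float), rng.integers(1, 50, 25).astype(float)
        ea, eb = rng.random(20) < 0.7, rng.random(25) < 0.7
        assert logrank_test(ta, ea, tb, eb) == pytest.approx(logrank_test(tb, eb, ta, ea))

    def test_separated_groups_match_hand_tabulation(self):
        """Events at {1,2,3} vs {10,11,12} reproduce the O-E/V table oracle."""
        ta, tb = np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])
        ea = eb = np.array([True, True, True])
        stat, p = logrank_test(ta, ea, tb, eb)
        time = np.concatenate([ta, tb])
        event = np.concatenate([ea, eb])
        group = np.array([True] * 3 + [False] * 3)
        stat_o, p_o = oracles.logrank_oracle(time, event, group)
        assert stat == pytest.approx(stat_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10)

    def test_empty_group_and_no_events_rejected(self):
        t = np.array([1.0, 2.0])
        e = np.array([True, False])
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test(t, e, np.array([]), np.array([], dtype=bool))
        with pytest.raises(ValueError, match="event"):
            logrank_test(t, ~e & False, t, np.zeros(2, dtype=bool))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scan_matches_oracle_with_ties_and_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        surv = SurvivalData(
            time=rng.integers(1, 15, n).astype(float),  # heavy ties
            event=rng.random(n) < 0.6,
        )
        membership = rng.random((n, 25)) < 0.5
        keep = (membership.sum(0) > 0) & (membership.sum(0) < n)
        membership = membership[:, keep]
        chi, pvals = logrank_scan(surv.time, surv.event, membership)
        for g in range(membership.shape[1]):
            chi_o, p_o = oracles.logrank_oracle(surv.time, surv.event, membership[:, g])
            assert chi[g] == pytest.approx(chi_o, rel=1e-9, abs=1e-12)
            assert pvals[g] == pytest.approx(p_o, rel=1e-9, abs=1e-300)

    def test_scan_agrees_with_lifelines(self):
        rng = np.random.default_rng(11)
        surv = _random_survival(rng, 60)
        membership = (rng.random((60, 10)) < 0.5)
        chi, pvals = logrank_scan(surv.time, surv.event, membership)
        for g in range(10):
            m = membership[:, g]
            if m.sum() in (0, 60):
                continue
            stat, p = logrank_test(surv.time[m], surv.event[m], surv.time[~m], surv.event[~m])
            assert chi[g] == pytest.approx(stat, rel=1e-9)
            assert pvals[g] == pytest.approx(p, rel=1e-9)

    def test_asymptotic_p_tracks_permutation_reference(self):
        """Chi-square p close to a 10^4-draw permutation reference at n=30."""
        rng = np.random.default_rng(17)
        surv = _random_survival(rng, 30)
        group = rng.random(30) < 0.5
        _, p = logrank_test(
            surv.time[group], surv.event[group], surv.time[~group], surv.event[~group]
        )
        p_perm = oracles.permutation_logrank_p(surv.time, surv.event, group, 10_000, seed=1)
        assert abs(p - p_perm) < 0.03  # asymptotic vs resampling approximation

    def test_zero_variance_grouping_returns_null(self):
        surv = SurvivalData(time=np.array([3.0, 4.0, 5.0]), event=np.array([True, True, False]))
        chi, p = logrank_scan(surv.time, surv.event, np.zeros((3, 1), dtype=bool))
        assert chi[0] == 0.0 and p[0] == 1.0


class TestSingleSplit:
    def test_single_candidate_forced(self):
        rng = np.random.default_rng(1)
        surv = _random_survival(rng, 40)
        values = rng.random(40)
        rule = GridRule(candidates=(0.5,), min_group_size=1)
        res = best_single_split(values, surv, rule, variable="v")
        assert res.threshold == 0.5
        assert res.group_sizes == ((values >= 0.5).sum(), (values < 0.5).sum())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        surv = _random_survival(rng, n)
        values = np.round(rng.random(n) * 10, 1)
        rule = GridRule(min_group_size=5)
        res = best_single_split(values, surv, rule, variable="v")
        cand = rule.candidate_thresholds(values)
        t_o, p_o = oracles.best_single_oracle(values, surv.time, surv.event, cand, 5)
        assert res.threshold == pytest.approx(t_o)
        assert res.p_value == pytest.approx(p_o, rel=1e-9)

    def test_event_indicator_variable_minimizes_over_grid(self):
        rng = np.random.default_rng(6)
        surv = _random_survival(rng, 60)
        values = surv.event.astype(float)
        rule = GridRule(candidates=(0.0, 0.5, 1.0), min_group_size=1)
        res = best_single_split(values, surv, rule)
        cand = [0.0, 0.5, 1.0]
        _, p_o = oracles.best_single_oracle(values, surv.time, surv.event, cand, 1)
        assert res.p_value == pytest.approx(p_o, rel=1e-9)

    def test_constant_variable_rejected(self):
        surv = SurvivalData(time=np.arange(1.0, 21.0), event=np.ones(20, dtype=bool))
        with pytest.raises(NoValidSplitError, match="constant"):
            best_single_split(np.full(20, 3.0), surv, variable="flat")

    def test_tie_breaks_toward_smaller_threshold(self):
        # two candidates inducing the identical partition -> identical p
        values = np.array([1.0] * 10 + [5.0] * 10)
        surv = SurvivalData(
            time=np.arange(1.0, 21.0), event=np.array([True] * 10 + [False] * 10)
        )
        rule = GridRule(candidates=(2.0, 3.0), min_group_size=1)
        res = best_single_split(values, surv, rule)
        assert res.threshold == 2.0

    def test_monotone_grid_refinement(self):
        rng = np.random.default_rng(9)
        surv = _random_survival(rng, 50)
        values = rng.random(50) * 10
        coarse = tuple(np.quantile(values, [0.3, 0.5, 0.7]))
        fine = coarse + tuple(np.quantile(values, [0.2, 0.4, 0.6, 0.8]))
        p_coarse = best_single_split(values, surv, GridRule(candidates=coarse, min_group_size=5)).p_value
        p_fine = best_single_split(values, surv, GridRule(candidates=fine, min_group_size=5)).p_value
        assert p_fine <= p_coarse + 1e-15


class TestPairSplit:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        surv = _random_survival(rng, n)
        v1 = np.round(rng.random(n) * 10, 1)
        v2 = np.round(rng.random(n) * 5, 1)
        rule = GridRule(min_group_size=4, max_candidates=None)
        res = best_pair_split(v1, v2, surv, rule)
        c1 = rule.candidate_thresholds(v1)
        c2 = rule.candidate_thresholds(v2)
        t1_o, t2_o, q_o, p_o = oracles.best_pair_oracle(
            v1, v2, surv.time, surv.event, c1, c2, 4
        )
        assert res.p_value == pytest.approx(p_o, rel=1e-9)

    def test_constant_second_variable_reduces_to_single_split(self):
        rng = np.random.default_rng(4)
        n = 60
        surv = _random_survival(rng, n)
        v1 = rng.random(n) * 10
        v2 = np.full(n, 7.0)
        rule = GridRule(min_group_size=5)
        pair = best_pair_split(v1, v2, surv, rule)
        single = best_single_split(v1, surv, rule)
        assert pair.p_value == pytest.approx(single.p_value, rel=1e-12)
        assert pair.threshold1 == pytest.approx(single.threshold)

    def test_planted_quadrant_wins(self):
        """With a planted high-RDW/low-HGB effect, Q1 wins in >= 90% of seeds."""
        wins = 0
        for seed in range(20):
            cfg = GeneratorConfig(
                n_patients=400, seed=500 + seed, interaction_effect=STRONG_INTERACTION
            )
            patients, events, _ = generate_cohort(cfg)
            labels = label_cohort(patients, events)
            feats = derive_features(patients, events)
            surv = survival_from_labels(labels)
            pair = best_pair_split(
                feats["RDW"].to_numpy(), feats["HGB"].to_numpy(), surv,
                GridRule(max_candidates=20),
            )
            wins += pair.quadrant == "Q1"
        assert wins >= 18


class TestSynergyScore:
    def test_reported_pair_values(self):
        assert synergy_score(2.74e-9, 6.82e-3, 4.67e-15) == pytest.approx(4001, rel=5e-3)
        assert synergy_score(1.25e-12, 6.82e-3, 2.59e-15) == pytest.approx(3.29, rel=1e-2)

    @given(p1=st.floats(1e-150, 1.0), p2=st.floats(1e-150, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_independence_identity(self, p1, p2):
        assert synergy_score(p1, p2, p1 * p2) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0.0, 0.5, 0.1), (0.5, 1.5, 0.1), (0.5, 0.5, -1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            synergy_score(*bad)

    def test_synergy_identity_holds_to_float_precision(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p1, p2, p12 = 10 ** (-rng.random(3) * 12)
            s = synergy_score(p1, p2, p12)
            assert s * p12 == pytest.approx(p1 * p2, rel=1e-12)


class TestQuadrantEnrichment:
    def test_direct_count_example(self):
        # 10 patients, 5 resistant; Q1 (v1 high, v2 low) holds 2, both resistant
        v1 = np.array([9, 9, 1, 1, 1, 1, 9, 9, 1, 1], dtype=float)
        v2 = np.array([0, 0, 9, 9, 0, 0, 9, 9, 0, 0], dtype=float)
        res = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        enrich, counts = quadrant_enrichment(v1, v2, 5.0, 5.0, res)
        assert counts["Q1"] == (2, 2)
        assert enrich["Q1"] == pytest.approx(2.0)

    def test_null_large_sample_near_one(self):
        rng = np.random.default_rng(10)
        n = 20_000
        v1, v2 = rng.random(n), rng.random(n)
        res = rng.random(n) < 0.4
        enrich, _ = quadrant_enrichment(v1, v2, 0.5, 0.5, res)
        for q in enrich:
            assert enrich[q] == pytest.approx(1.0, abs=0.05)

    def test_empty_quadrant_is_nan(self):
        v1 = np.array([1.0, 1.0, 1.0, 1.0])
        v2 = np.array([9.0, 9.0, 0.0, 0.0])
        res = np.array([True, False, True, False])
        enrich, counts = quadrant_enrichment(v1, v2, 5.0, 5.0, res)
        assert counts["Q1"] == (0, 0) and np.isnan(enrich["Q1"])

    def test_conservation_weighted_mean_is_one(self):
        rng = np.random.default_rng(13)
        n = 500
        v1, v2 = rng.random(n), rng.random(n)
        res = rng.random(n) < 0.3
        enrich, counts = quadrant_enrichment(v1, v2, 0.4, 0.6, res)
        total = sum(counts[q][0] for q in counts)
        weighted = sum(counts[q][0] * enrich[q] for q in counts) / total
        assert weighted == pytest.approx(1.0, rel=1e-12)

    def test_zero_prevalence_rejected(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="resistant"):
            quadrant_enrichment(v, v, 2.0, 2.0, np.zeros(4, dtype=bool))


class TestRankPairs:
    def test_pair_count_and_sort_orders(self):
        rng = np.random.default_rng(14)
        n = 200
        surv = _random_survival(rng, n)
        feats = pd.DataFrame(rng.random((n, 5)) * 10, columns=list("abcde"))
        pairs, assoc = rank_pairs(feats, surv, grid_rule=GridRule(min_group_size=10))
        assert len(pairs) == 10  # C(5, 2)
        assert (pairs["synergy"].to_numpy() == np.sort(pairs["synergy"])[::-1]).all()
        assert (assoc["p12"].to_numpy() == np.sort(assoc["p12"])).all()

    def test_missing_rows_dropped_pairwise_complete(self):
        rng = np.random.default_rng(15)
        n = 120
        surv = _random_survival(rng, n)
        feats = pd.DataFrame(rng.random((n, 3)) * 10, columns=list("abc"))
        feats.loc[:4, "a"] = np.nan
        pairs, _ = rank_pairs(feats, surv)
        assert len(pairs) == 3  # still all pairs, on complete cases

    def test_all_noise_top_synergy_stays_moderate(self):
        """Empirical null bound: median top synergy across seeds below 100."""
        tops = []
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            n = 150
            surv = _random_survival(rng, n)
            feats = pd.DataFrame(rng.random((n, 5)) * 10, columns=list("vwxyz"))
            pairs, _ = rank_pairs(feats, surv)
            tops.append(pairs["synergy"].iloc[0])
        assert np.median(tops) < 100
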