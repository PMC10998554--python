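"""Secretion tiering, gated-population statistics, ranking, recovery rates,
quadrant gating and purity."""

from itertools import combinations

import numpy as np
import pytest

from nanotcr import (ChainKey, Clonotype, SecretionAnnotation, TierThresholds,
                     ValidationError, annotate_secretion, classify_quadrant,
                     classify_quadrants, classify_tier, clonotype_secretion_level,
                     compare_gated_populations, compute_purity, lognormal_params,
                     rank_candidates, recovery_rate, tier_summary)


class TestTierClassification:
    @pytest.mark.parametrize("level,tier", [
        (0, "Low"), (288, "Low"), (499, "Low"),
        (500, "Medium"), (1999, "Medium"),
        (2000, "High"), (10_000, "High"),
    ])
    def test_boundaries(self, level, tier):
        assert classify_tier(level) == tier

    def test_open_high_bound_variant(self):
        t = TierThresholds(high_inclusive=False)
        assert classify_tier(2000, t) == "Medium"
        assert classify_tier(2001, t) == "High"

    def test_negative_level_rejected(self):
        with pytest.raises(ValidationError):
            classify_tier(-1)

    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            TierThresholds(high_min=400, medium_min=500)

    def test_monotone_in_level(self):
        order = {"Low": 0, "Medium": 1, "High": 2}
        tiers = [order[classify_tier(lvl)] for lvl in range(0, 5000, 7)]
        assert tiers == sorted(tiers)


def _annotations(n_high, n_medium, n_low):
    levels = [2500] * n_high + [1000] * n_medium + [100] * n_low
    return annotate_secretion({f"c{i}": lvl for i, lvl in enumerate(levels)})


class TestTierSummary:
    def test_counts_and_half_up_percentages(self):
        summary = tier_summary(_annotations(9, 40, 19))
        assert summary["High"] == {"count": 9, "percent": 13.2}
        assert summary["Medium"] == {"count": 40, "percent": 58.8}
        assert summary["Low"] == {"count": 19, "percent": 27.9}

    def test_single_subject(self):
        summary = tier_summary(_annotations(0, 1, 0))
        assert summary["Medium"]["percent"] == 100.0

    def test_counts_conserved_and_percentages_near_100(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(1, 200, size=3)
            summary = tier_summary(_annotations(*n))
            assert sum(v["count"] for v in summary.values()) == n.sum()
            assert abs(sum(v["percent"] for v in summary.values()) - 100) <= 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            tier_summary([])


class TestGatedComparison:
    def test_identical_populations(self):
        out = compare_gated_populations([5, 5, 5], [5, 5, 5])
        assert out["p_value"] >= 0.99

    def test_brute_force_u_statistic(self):
        """U for pos={3,4,5} vs neg={1,1,2} by exhaustive rank enumeration."""
        pos, neg = [3, 4, 5], [1, 1, 2]
        u_brute = sum((1.0 if p > n else 0.5 if p == n else 0.0)
                      for p in pos for n in neg)
        assert u_brute == 9.0
        from scipy.stats import mannwhitneyu
        assert mannwhitneyu(pos, neg, alternative="two-sided").statistic == u_brute
        out = compare_gated_populations(pos, neg)
        assert out["mean_pos"] == 4.0
        assert out["mean_neg"] == pytest.approx(4 / 3)

    def test_sample_sd_uses_n_minus_1(self):
        out = compare_gated_populations([1, 3], [2, 2, 5])
        assert out["sd_pos"] == pytest.approx(np.std([1, 3], ddof=1))
        assert out["sd_neg"] == pytest.approx(np.std([2, 2, 5], ddof=1))

    def test_matched_moment_cohorts_significant(self):
        """Cohorts drawn from the gate-matched log-normal laws separate at
        p < 1e-4, in the direction of the positive gate."""
        rng = np.random.default_rng(42)
        mu_p, s_p = lognormal_params(1022, 1286)
        mu_n, s_n = lognormal_params(288, 149)
        pos = np.floor(rng.lognormal(mu_p, s_p, 500)).astype(int)
        neg = np.floor(rng.lognormal(mu_n, s_n, 500)).astype(int)
        out = compare_gated_populations(pos, neg)
        assert out["mean_pos"] > out["mean_neg"]
        assert out["p_value"] < 1e-4

    def test_welch_variant(self):
        out = compare_gated_populations([1, 2, 3], [7, 8, 9], test="welch")
        assert out["p_value"] < 0.05

    def test_too_small(self):
        with pytest.raises(ValidationError):
            compare_gated_populations([1], [2, 3])


def _clone(cid, barcodes):
    return Clonotype(cid, frozenset([ChainKey("TRA", "V", "J", cid)]),
                     frozenset([ChainKey("TRB", "V", "J", cid)]),
                     frozenset(barcodes))


class TestRanking:
    def setup_method(self):
        self.clones = [_clone("c1", ["a-1"]), _clone("c2", ["b-1"]),
                       _clone("c3", ["c-1"])]
        self.levels = {"a-1": 2500, "b-1": 1900, "c-1": 2100}

    def test_min_level_filter_and_order(self):
        out = rank_candidates(self.clones, self.levels, by="secretion",
                              top_n=6, min_level=2000)
        assert [r[0] for r in out] == ["c1", "c3"]

    def test_top_n_larger_than_input(self):
        out = rank_candidates(self.clones, self.levels, top_n=100)
        assert [r[0] for r in out] == ["c1", "c3", "c2"]

    def test_frequency_ranking(self):
        clones = [_clone("c1", ["a-1"]), _clone("c2", ["b-1", "c-1"])]
        out = rank_candidates(clones, self.levels, by="frequency", top_n=1)
        assert out[0][0] == "c2"

    def test_max_vs_mean_aggregation(self):
        clone = _clone("c1", ["a-1", "b-1"])
        assert clonotype_secretion_level(clone, self.levels, "max") == 2500
        assert clonotype_secretion_level(clone, self.levels, "mean") == 2200

    def test_disjoint_secretion_and_frequency_lists(self):
        """When high secretors are rare singleton clones, the secretion-ranked
        and frequency-ranked candidate lists do not overlap."""
        clones, levels = [], {}
        for i in range(15):  # expanded clones, low secretion
            cells = [f"f{i}_{j}-1" for j in range(10 + i)]
            clones.append(_clone(f"freq{i:02d}", cells))
            levels.update({c: 300 + i for c in cells})
        for i in range(6):   # rare clones, high secretion
            clones.append(_clone(f"rare{i}", [f"r{i}-1"]))
            levels[f"r{i}-1"] = 2100 + i
        top_secretion = {r[0] for r in rank_candidates(
            clones, levels, by="secretion", top_n=6, min_level=2000)}
        top_frequency = {r[0] for r in rank_candidates(
            clones, levels, by="frequency", top_n=15)}
        assert top_secretion and top_secretion.isdisjoint(top_frequency)

    def test_missing_annotation(self):
        with pytest.raises(ValidationError):
            rank_candidates([_clone("c9", ["zz-1"])], {}, top_n=1)


class TestRecoveryRate:
    def _candidates(self):
        cands = [SecretionAnnotation(f"H{i}", 2500, "High") for i in range(6)]
        cands += [SecretionAnnotation(f"M{i}", 1000, "Medium") for i in range(15)]
        cands += [SecretionAnnotation(f"L{i}", 100, "Low") for i in range(4)]
        labels = {c.subject_id: False for c in cands}
        labels["H0"] = labels["H1"] = labels["M0"] = True
        return cands, labels

    def test_per_tier_rates(self):
        cands, labels = self._candidates()
        report = recovery_rate(cands, labels)
        assert report.per_tier["High"].rate == pytest.approx(1 / 3)
        assert report.per_tier["Medium"].rate == pytest.approx(1 / 15)
        assert report.per_tier["Low"].rate == 0.0
        assert all(0 <= t.rate <= 1 for t in report.per_tier.values())

    def test_order_invariant(self):
        cands, labels = self._candidates()
        assert recovery_rate(cands[::-1], labels) == recovery_rate(cands, labels)

    def test_zero_tested_flagged(self):
        report = recovery_rate([SecretionAnnotation("H0", 2500, "High")], {"H0": True})
        assert report.per_tier["Low"].undefined
        assert report.per_tier["Low"].rate == 0.0

    def test_missing_label(self):
        with pytest.raises(ValidationError):
            recovery_rate([SecretionAnnotation("x", 0, "Low")], {})


class TestQuadrants:
    @pytest.mark.parametrize("a,b,quadrant", [
        (5, 1, "Q1"), (5, 5, "Q2"), (1, 5, "Q3"), (1, 1, "Q4"),
        (2, 2, "Q4"),  # both exactly at threshold fall in the lower class
        (5, 2, "Q1"), (2, 5, "Q3"),
    ])
    def test_gate_assignment(self, a, b, quadrant):
        assert classify_quadrant(a, b, 2.0, 2.0) == quadrant

    def test_partition_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(0)
        events = {f"e{i}": (rng.exponential(2), rng.exponential(2))
                  for i in range(1000)}
        labels = classify_quadrants(events, 2.0, 2.0)
        assert len(labels) == 1000
        counts = {q: 0 for q in ("Q1", "Q2", "Q3", "Q4")}
        for lab in labels:
            counts[lab.quadrant] += 1
        assert sum(counts.values()) == 1000
        # exclusivity: one label per subject
        assert len({lab.subject_id for lab in labels}) == 1000


class TestPurity:
    def test_subset_is_pure(self):
        assert compute_purity({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_printed_example(self):
        selected = {f"s{i}" for i in range(100)}
        positive = {f"s{i}" for i in range(94)} | {"other"}
        assert compute_purity(selected, positive) == 0.94

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sel = {f"x{i}" for i in rng.integers(0, 50, size=20)}
            pos = {f"x{i}" for i in rng.integers(0, 50, size=20)}
            expected = sum(1 for s in sel if s in pos) / len(sel)
            assert compute_purity(sel, pos) == expected

    def test_empty_selection(self):
        with pytest.raises(ValidationError):
            compute_purity(set(), {"a"})
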