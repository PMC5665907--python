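"""Population statistics: prevalence, index, tests, regression, contexts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editaccess.popstats import (
    EditingMatrix,
    compute_rpkm,
    context_enrichment,
    differential_editing,
    editing_index,
    mean_editing_per_individual,
    minimum_detectable_delta,
    overlap_test,
    paired_window_profile,
    population_correlation_contrast,
    prevalence,
    rank_sum_test,
    variance_explained,
)


def build_matrix(alts_rows, depths_rows, populations):
    individuals = [f"i{j}" for j in range(len(populations))]
    sites = [f"s{k}" for k in range(len(alts_rows))]
    return EditingMatrix.from_counts(
        pd.DataFrame(alts_rows, index=sites, columns=individuals),
        pd.DataFrame(depths_rows, index=sites, columns=individuals),
        pd.Series(populations, index=individuals),
    )


class TestPrevalence:
    def test_denominator_is_testable_individuals(self):
        """5 edited of 10 testable (out of 20 total) -> 50%."""
        n = 20
        depths = [20] * 10 + [5] * 10
        alts = [4] * 5 + [0] * 15
        m = build_matrix([alts], [depths], ["P"] * n)
        rec = prevalence(m, "s0")
        assert rec.percent == pytest.approx(50.0)
        assert rec.n_testable == 10 and rec.n_edited == 5

    def test_prevalent_cut_is_strict(self):
        m = build_matrix([[5] * 91 + [0] * 9], [[20] * 100], ["P"] * 100)
        assert prevalence(m, "s0").category == "prevalent"
        m = build_matrix([[5] * 90 + [0] * 10], [[20] * 100], ["P"] * 100)
        assert prevalence(m, "s0").category == "intermediate"

    def test_zero_testable_flagged(self):
        m = build_matrix([[0, 0]], [[5, 5]], ["P", "P"])
        assert prevalence(m, "s0").category == "untestable"

    def test_monotone_in_edited_individuals(self):
        base_alts = [4] * 5 + [0] * 5
        depths = [20] * 10
        before = prevalence(build_matrix([base_alts], [depths], ["P"] * 10), "s0")
        flipped = list(base_alts)
        flipped[7] = 4  # one testable-unedited individual becomes edited
        after = prevalence(build_matrix([flipped], [depths], ["P"] * 10), "s0")
        assert after.percent >= before.percent


class TestMeanAndIndex:
    def test_unweighted_mean(self):
        m = build_matrix([[2], [6]], [[20], [20]], ["P"])
        assert mean_editing_per_individual(m, "i0") == pytest.approx(0.2)

    def test_index_equals_mean_at_equal_depth(self):
        m = build_matrix([[2], [18]], [[20], [20]], ["P"])
        assert editing_index(m, "i0") == pytest.approx(0.5)
        assert mean_editing_per_individual(m, "i0") == pytest.approx(0.5)

    def test_index_departs_from_mean_under_unequal_depth(self):
        m = build_matrix([[2], [2]], [[10], [100]], ["P"])
        assert editing_index(m, "i0") == pytest.approx(4 / 110)
        assert mean_editing_per_individual(m, "i0") == pytest.approx(0.11)

    def test_no_testable_sites_missing(self):
        m = build_matrix([[1]], [[5]], ["P"])
        assert math.isnan(mean_editing_per_individual(m, "i0"))
        assert math.isnan(editing_index(m, "i0"))


def hypergeom_tail_oracle(overlap, n_bg, n_a, n_b):
    """Brute-force upper tail: sum point masses over the support."""
    total = 0.0
    for k in range(overlap, min(n_a, n_b) + 1):
        total += (
            math.comb(n_a, k)
            * math.comb(n_bg - n_a, n_b - k)
            / math.comb(n_bg, n_b)
        )
    return total


class TestOverlapTest:
    def test_matches_bruteforce_enumeration(self):
        bg = list(range(20))
        a, b = set(range(8)), set(range(5, 15))
        ov, p = overlap_test(a, b, bg)
        assert ov == 3
        assert p == pytest.approx(hypergeom_tail_oracle(3, 20, 8, 10))

    def test_disjoint_sets_p_one(self):
        bg = list(range(20))
        ov, p = overlap_test(set(range(5)), set(range(10, 15)), bg)
        assert ov == 0 and p == pytest.approx(1.0)

    def test_degenerate_full_overlap(self):
        bg = list(range(12))
        ov, p = overlap_test(set(bg), set(bg), bg)
        assert ov == 12 and p == pytest.approx(1.0)

    def test_containment_enforced(self):
        with pytest.raises(ValueError):
            overlap_test({1, 99}, {1}, list(range(10)))


def ranksum_enumeration_oracle(x, y):
    """Exact two-sided p: count permutations at least as deviant (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    mu = nx * (len(pooled) + 1) / 2
    obs = abs(ranks[:nx].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    @pytest.mark.parametrize(
        "x,y",
        [
            ([1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 6.0, 8.0]),
            ([0.1, 0.1, 0.2, 0.5, 0.5], [0.2, 0.3, 0.3, 0.4]),  # ties
            (list(range(8)), [v + 2.5 for v in range(8)]),
        ],
    )
    def test_exact_branch_matches_enumeration(self, x, y):
        assert rank_sum_test(x, y) == pytest.approx(
            ranksum_enumeration_oracle(np.array(x), np.array(y))
        )

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)
        p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestDifferentialEditing:
    def test_identical_vectors_not_differential(self):
        m = build_matrix([[4] * 8], [[20] * 8], ["A"] * 4 + ["B"] * 4)
        res = differential_editing(m, "s0", ["i0", "i1", "i2", "i3"],
                                   ["i4", "i5", "i6", "i7"])
        assert res.delta == 0.0 and not res.is_differential

    def test_effect_size_floor_blocks_small_shifts(self):
        """Significant but tiny (delta = 0.05 < 0.067) shifts are not called."""
        a = [20, 20, 20, 20, 20, 20, 20, 20]
        b = [30, 30, 30, 30, 30, 30, 30, 30]
        m = build_matrix([a + b], [[200] * 16], ["A"] * 8 + ["B"] * 8)
        res = differential_editing(
            m, "s0", [f"i{j}" for j in range(8)], [f"i{j}" for j in range(8, 16)]
        )
        assert res.p < 0.01
        assert res.delta == pytest.approx(0.05)
        assert not res.is_differential

    def test_insufficient_group_untested(self):
        m = build_matrix([[4] * 4], [[20, 20, 5, 20]], ["A", "A", "A", "B"])
        res = differential_editing(m, "s0", ["i0", "i1", "i2"], ["i3"])
        assert not res.tested

    def test_floor_value_derivation(self):
        assert minimum_detectable_delta(15) == 0.067


class TestVarianceExplained:
    @staticmethod
    def adar_frame(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "ADAR1": rng.lognormal(2, 0.4, n),
                "ADAR2": rng.lognormal(0.5, 0.3, n),
                "ADAR3": rng.lognormal(-1, 0.5, n),
            },
            index=[f"i{j}" for j in range(n)],
        )

    def test_exact_linear_relationship(self):
        adar = self.adar_frame(50)
        levels = pd.Series(0.01 * adar["ADAR1"] + 0.05, index=adar.index)
        r2, _ = variance_explained(levels, adar)
        assert r2 == pytest.approx(1.0)

    def test_independent_levels_near_zero(self):
        adar = self.adar_frame(1000)
        rng = np.random.default_rng(1)
        levels = pd.Series(rng.uniform(0, 1, 1000), index=adar.index)
        r2, _ = variance_explained(levels, adar)
        assert r2 < 0.02

    def test_eligibility_needs_more_than_ten(self):
        adar = self.adar_frame(10)
        levels = pd.Series(np.linspace(0.1, 0.5, 10), index=adar.index)
        r2, reason = variance_explained(levels, adar)
        assert r2 is None and "10" in reason

    def test_constant_levels_skipped(self):
        adar = self.adar_frame(20)
        levels = pd.Series(0.3, index=adar.index)
        r2, reason = variance_explained(levels, adar)
        assert r2 is None and "distinct" in reason


def fisher_two_sided_oracle(a, b, c, d):
    """Sum of hypergeometric point masses not exceeding the observed one."""
    row1, row2, col1 = a + b, c + d, a + c
    n = a + b + c + d

    def mass(k):
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    observed = mass(a)
    lo, hi = max(0, col1 - row2), min(row1, col1)
    return sum(mass(k) for k in range(lo, hi + 1) if mass(k) <= observed * (1 + 1e-9))


class TestContextEnrichment:
    def test_identical_groups_null(self):
        ctx = ["UAG"] * 10 + ["CAG"] * 10
        table, p = context_enrichment(ctx, list(ctx))
        assert (table["difference"] == 0).all()
        assert p == pytest.approx(1.0)

    def test_fisher_matches_bruteforce(self):
        prev = ["UAG"] * 100 + ["CAA"] * 614
        rare = ["UAG"] * 200 + ["CAA"] * 3418
        _, p = context_enrichment(prev, rare)
        assert p == pytest.approx(fisher_two_sided_oracle(100, 614, 200, 3418), rel=1e-6)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            context_enrichment([], ["UAG"])

    def test_malformed_context_rejected(self):
        with pytest.raises(ValueError):
            context_enrichment(["UUG"], ["UAG"])  # centre is not A


class TestPairedWindowProfile:
    def test_unpaired_structure_gives_zero(self):
        pt = np.full(101, -1)
        prof = paired_window_profile([pt], [50], max_offset=10)
        assert (prof["mean_paired"].dropna() == 0).all()

    def test_perfect_helix_counts_window(self):
        pt = np.full(101, -1)
        for i in range(46, 55):  # 9 consecutive paired positions
            pt[i] = 100 - i + 40  # arbitrary partners
        prof = paired_window_profile([pt], [50], max_offset=5)
        assert prof.loc[prof.offset == 0, "mean_paired"].item() == 9

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(2)
        pt = np.where(rng.random(80) < 0.4, rng.integers(0, 80, 80), -1)
        site = 40
        prof = paired_window_profile([pt], [site], max_offset=8)
        for _, row in prof.iterrows():
            c = site + int(row.offset)
            expected = int(np.sum(pt[c - 4 : c + 5] >= 0))
            assert row.mean_paired == expected

    def test_window_past_edge_skipped(self):
        pt = np.full(20, 3)
        prof = paired_window_profile([pt], [2], max_offset=5)
        assert prof.loc[prof.offset == -5, "n"].item() == 0


class TestRPKM:
    def test_formula(self):
        assert compute_rpkm(np.array([1000.0]), np.array([1000.0]), 1e6)[0] == 1000.0

    def test_zero_counts(self):
        assert compute_rpkm(np.array([0.0]), np.array([500.0]), 1e6)[0] == 0.0

    def test_scaling_in_total(self):
        one = compute_rpkm(np.array([100.0]), np.array([2000.0]), 1e6)
        two = compute_rpkm(np.array([100.0]), np.array([2000.0]), 2e6)
        assert one[0] == pytest.approx(2 * two[0])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(np.array([1.0]), np.array([0.0]), 1e6)


class TestPopulationCorrelationContrast:
    def test_population_specific_effects_raise_intra_correlation(self):
        rng = np.random.default_rng(5)
        n_sites, n_per_pop = 60, 12
        site_base = rng.uniform(0.1, 0.5, n_sites)
        pop_effect = {"A": rng.normal(0, 0.1, n_sites), "B": rng.normal(0, 0.1, n_sites)}
        levels, pops = [], []
        for pop in ("A", "B"):
            for _ in range(n_per_pop):
                lv = np.clip(site_base + pop_effect[pop] + rng.normal(0, 0.03, n_sites), 0, 1)
                levels.append(lv)
                pops.append(pop)
        depth = np.full(n_sites, 50)
        individuals = [f"i{j}" for j in range(len(pops))]
        lv = pd.DataFrame(np.array(levels).T, columns=individuals)
        m = EditingMatrix(
            levels=lv,
            depths=pd.DataFrame(
                np.tile(depth[:, None], len(pops)), columns=individuals
            ),
            alts=(lv * 50).round(),
            populations=pd.Series(pops, index=individuals),
        )
        intra, inter = population_correlation_contrast(m)
        assert intra > inter
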