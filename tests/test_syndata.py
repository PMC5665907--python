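"""Synthetic-data generator: populations, hairpins, degradation, pileups."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editaccess.structacc import fold_window, opposite_nucleotide
from editaccess.syndata import (
    CohortParams,
    DegradationParams,
    PopulationSimConfig,
    apply_degradation,
    default_population_config,
    editing_accessibility_profile,
    generate_annotation_tracks,
    generate_hairpin_utr,
    generate_population,
    make_gene_panel,
    revcomp,
    simulate_cohort,
    simulate_pileup,
    survival_from_accessibility,
)


def two_pop_config(delta_loc=0.5, n=100, seed=0):
    expr = {
        "ADAR1": {"P1": (2.0, 0.3), "P2": (2.0 + delta_loc, 0.3)},
        "AGO2": {"P1": (1.5, 0.4), "P2": (1.5, 0.4)},
    }
    return PopulationSimConfig(
        populations={"P1": n, "P2": n}, expression=expr, seed=seed
    )


class TestGeneratePopulation:
    def test_configured_location_shift_detectable(self):
        """ADAR1 locations 0.5 log-units apart separate the groups (t-test)."""
        table = generate_population(two_pop_config())
        a = np.log(table.loc[table.population == "P1", "ADAR1"])
        b = np.log(table.loc[table.population == "P2", "ADAR1"])
        t, p = stats.ttest_ind(a, b)
        assert p < 0.01
        assert a.mean() < b.mean()

    def test_one_row_per_individual(self):
        table = generate_population(two_pop_config(n=1))
        assert len(table) == 2
        assert set(table.population) == {"P1", "P2"}

    def test_same_seed_identical(self):
        t1 = generate_population(two_pop_config(seed=7))
        t2 = generate_population(two_pop_config(seed=7))
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"populations": {"P": 0}},
            {"error_rate": 0.6},
            {"degradation_k": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(
            populations={"P": 2},
            expression={"ADAR1": {"P": (1.0, 0.5)}},
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            PopulationSimConfig(**base)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            PopulationSimConfig(
                populations={"P": 2}, expression={"ADAR1": {"P": (1.0, 0.0)}}
            )


class TestHairpinDesign:
    def test_opposite_c_toggles_pairing(self, engine):
        """A.C mismatch: site unpaired when unedited, G-C paired when edited."""
        t = generate_hairpin_utr(edit_opposite="C", seed=11)
        unedited, edited, start = fold_window(t.sequence, t.edit_pos, 1001, engine)
        pos = t.edit_pos - start
        assert not unedited.is_paired(pos)
        assert edited.is_paired(pos)
        assert edited.sequence[edited.pair_table[pos]] == "C"

    def test_opposite_u_gives_wobble_when_edited(self, engine):
        t = generate_hairpin_utr(edit_opposite="U", seed=12)
        unedited, edited, start = fold_window(t.sequence, t.edit_pos, 1001, engine)
        pos = t.edit_pos - start
        assert unedited.is_paired(pos)  # A-U pair
        assert edited.is_paired(pos)  # G.U wobble
        assert edited.sequence[edited.pair_table[pos]] == "U"

    def test_seed_overlap_requires_flag(self):
        with pytest.raises(ValueError, match="seed"):
            generate_hairpin_utr(target_distance=0)
        t = generate_hairpin_utr(target_distance=0, allow_seed_overlap=True)
        s, e = t.target_interval
        assert s <= t.edit_pos < e

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nfeasible|exceed"):
            generate_hairpin_utr(target_distance=3)  # inside the stem half
        with pytest.raises(ValueError, match="infeasible"):
            generate_hairpin_utr(length=50)

    def test_designed_distance_convention(self):
        """Edge-to-edge distance between site and seed interval is honoured."""
        t = generate_hairpin_utr(target_distance=25, seed=3)
        s, e = t.target_interval
        assert t.edit_pos - (e - 1) == 25
        seed_site = revcomp(t.sequence[s:e])  # should be miRNA nt 2-8
        assert len(seed_site) == 7

    def test_sequence_invariants(self):
        t = generate_hairpin_utr(seed=5)
        assert t.sequence[t.edit_pos] == "A"
        assert 0 <= t.target_interval[0] < t.target_interval[1] <= len(t.sequence)


class TestDegradationModel:
    def test_closed_form_spot_value(self):
        obs, ab = apply_degradation(DegradationParams(e=0.2, s_u=0.5, s_e=1.0))
        assert obs == pytest.approx(1.0 / 3.0)
        assert ab == pytest.approx(0.6)

    def test_equal_survival_is_identity(self):
        for e in (0.0, 0.3, 1.0):
            obs, _ = apply_degradation(DegradationParams(e=e, s_u=0.7, s_e=0.7))
            assert obs == pytest.approx(e)

    def test_zero_editing_stays_zero(self):
        obs, _ = apply_degradation(DegradationParams(e=0.0, s_u=0.2, s_e=0.9))
        assert obs == 0.0

    def test_observed_never_below_true_when_edited_survive_better(self):
        for e in np.linspace(0.05, 0.95, 10):
            for s_u in np.linspace(0.1, 0.9, 9):
                obs, _ = apply_degradation(DegradationParams(e=e, s_u=s_u, s_e=1.0))
                assert obs >= e

    def test_ratio_compression(self):
        """Degradation buffers differences: observed ratios shrink."""
        grid = np.linspace(0.05, 0.95, 10)
        for s_u in np.linspace(0.1, 0.9, 9):
            for i, e1 in enumerate(grid[:-1]):
                for e2 in grid[i + 1 :]:
                    o1, _ = apply_degradation(DegradationParams(e=e1, s_u=s_u, s_e=1.0))
                    o2, _ = apply_degradation(DegradationParams(e=e2, s_u=s_u, s_e=1.0))
                    assert o2 / o1 < e2 / e1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DegradationParams(e=1.2, s_u=0.5, s_e=0.5)
        with pytest.raises(ValueError):
            DegradationParams(e=0.5, s_u=0.0, s_e=0.5)


class TestSurvivalLink:
    def test_no_degradation_at_k_zero(self):
        assert survival_from_accessibility(5.0, 0.3, 0.0) == 1.0

    def test_closed_form(self):
        assert survival_from_accessibility(1.0, 0.5, 1.0) == pytest.approx(
            math.exp(-0.5)
        )

    def test_monotone_in_accessibility(self):
        s_hi = survival_from_accessibility(1.0, 0.9, 1.0)
        s_lo = survival_from_accessibility(1.0, 0.2, 1.0)
        assert s_hi < s_lo  # more accessible -> less survival

    def test_input_validation(self):
        with pytest.raises(ValueError):
            survival_from_accessibility(-1.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            survival_from_accessibility(1.0, 0.0, 1.0)

    def test_accessibility_profile_decays_with_distance(self):
        u0, e0 = editing_accessibility_profile(0)
        u90, e90 = editing_accessibility_profile(90)
        assert u0 == u90  # unedited baseline unchanged
        assert e0 < e90 < u90  # edit effect strongest at the site


class TestSimulatePileup:
    def test_binomial_sampling_mean(self):
        alts = [
            simulate_pileup(0.5, 100, error_rate=0.0, seed=s).alt_count
            for s in range(200)
        ]
        assert 45 <= np.mean(alts) <= 55

    def test_no_editing_no_errors_gives_zero(self):
        obs = simulate_pileup(0.0, 50, error_rate=0.0, seed=1)
        assert obs.alt_count == 0

    def test_zero_depth_untestable(self):
        obs = simulate_pileup(0.5, 0, seed=1)
        assert obs.depth == 0 and obs.alt_count == 0
        assert not obs.testable

    def test_quality_per_alt_read_and_determinism(self):
        a = simulate_pileup(0.3, 40, seed=9)
        b = simulate_pileup(0.3, 40, seed=9)
        assert a == b
        assert len(a.quals) == a.alt_count
        assert all(2 <= q <= 41 for q in a.quals)


class TestAnnotationTracks:
    def test_homopolymer_computed_from_sequence(self):
        tracks = generate_annotation_tracks({"g": "CCGAAAAAGCC"})
        assert tracks.homopolymers["g"] == [(3, 8)]

    def test_zero_snp_density_empty_track(self):
        tracks = generate_annotation_tracks({"g": "ACGU" * 30}, snp_density=0.0)
        assert tracks.snps["g"] == set()

    def test_deterministic_per_seed(self):
        seqs = {"g": "ACGU" * 50}
        t1 = generate_annotation_tracks(seqs, snp_density=0.2, seed=4)
        t2 = generate_annotation_tracks(seqs, snp_density=0.2, seed=4)
        assert t1.snps == t2.snps

    def test_snp_never_on_designed_editing_site(self):
        t = generate_hairpin_utr(seed=0)
        tracks = generate_annotation_tracks([t], snp_density=0.5, seed=0)
        assert t.edit_pos not in tracks.snps[t.gene_id]

    def test_out_of_bounds_repeat_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            generate_annotation_tracks({"g": "ACGU"}, repeat_spec={"g": [(0, 10)]})


class TestCohort:
    def test_bitwise_reproducible(self):
        genes = make_gene_panel(3, 1, 1, utr_length=200, seed=5)
        profiles = generate_population(default_population_config(10, seed=5))
        acc = {
            g.gene_id: editing_accessibility_profile(g.target_distance or 50)
            for g in genes
            if g.target_interval is not None
        }
        c1 = simulate_cohort(profiles, genes, acc, CohortParams(), seed=5)
        c2 = simulate_cohort(profiles, genes, acc, CohortParams(), seed=5)
        pd.testing.assert_frame_equal(c1.observed_levels, c2.observed_levels)
        pd.testing.assert_frame_equal(c1.alts, c2.alts)

    def test_panel_composition(self):
        genes = make_gene_panel(4, 2, 3, utr_length=200, seed=1)
        has_both = [g for g in genes if g.edit_pos is not None and g.target_interval]
        no_target = [g for g in genes if g.edit_pos is not None and not g.target_interval]
        no_edit = [g for g in genes if g.edit_pos is None]
        assert (len(has_both), len(no_target), len(no_edit)) == (4, 2, 3)
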