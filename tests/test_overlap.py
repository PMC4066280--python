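"""Overlap statistics: hypergeometric tails, the running scan, concordance."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import sigoverlap as so
from sigoverlap.overlap import (
    hypergeom_upper_exact,
    log10_fraction,
    running_fisher_scan,
    scan_cutoffs,
)
from conftest import make_signature


def _pmf_sum_oracle(k, draws, successes, population):
    """Direct per-term PMF summation, independent of the implementation."""
    total = Fraction(0)
    denom = math.comb(population, draws)
    for i in range(k, min(draws, successes) + 1):
        a = math.comb(successes, i)
        b = math.comb(population - successes, draws - i)
        total += Fraction(a * b, denom)
    return total


class TestHypergeomUpper:
    def test_zero_overlap_gives_p_one(self):
        assert so.hypergeom_upper(0, 5, 6, 20) == 1.0

    def test_saturated_arguments_force_p_one(self):
        assert so.hypergeom_upper(5, 5, 5, 5) == 1.0

    def test_matches_direct_pmf_summation(self):
        assert hypergeom_upper_exact(4, 5, 6, 20) == _pmf_sum_oracle(4, 5, 6, 20)

    @pytest.mark.parametrize("k,draws,successes,population", [
        (3, 10, 8, 50), (1, 4, 4, 9), (7, 12, 20, 100), (0, 3, 3, 10), (2, 2, 2, 4),
    ])
    def test_agrees_with_scipy_survival_function(self, k, draws, successes, population):
        ours = so.hypergeom_upper(k, draws, successes, population)
        ref = stats.hypergeom.sf(k - 1, population, successes, draws)
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_log10_stays_finite_beyond_float_underflow(self):
        # 400 of 400 draws hitting 400 of 4000: astronomically small tail
        log10p = so.hypergeom_upper_log10(400, 400, 400, 4000)
        assert log10p < -300
        assert math.isfinite(log10p)
        assert so.hypergeom_upper(400, 400, 400, 4000) > 0  # floored, never zero

    def test_log10_consistent_with_float_in_moderate_range(self):
        p = so.hypergeom_upper(6, 10, 12, 60)
        assert so.hypergeom_upper_log10(6, 10, 12, 60) == pytest.approx(math.log10(p))

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            so.hypergeom_upper(6, 5, 6, 20)
        with pytest.raises(ValueError):
            so.hypergeom_upper(2, 30, 6, 20)


class TestScanGrid:
    def test_small_signatures_scan_every_rank(self):
        assert scan_cutoffs(12) == list(range(1, 13))
        assert scan_cutoffs(49) == list(range(1, 50))

    def test_large_signatures_scan_decile_boundaries(self):
        assert scan_cutoffs(100) == [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        assert scan_cutoffs(55) == [6, 11, 17, 22, 28, 33, 39, 44, 50, 55]


class TestRunningFisher:
    def test_disjoint_signatures_give_p_one(self):
        a = make_signature([f"a{i}" for i in range(8)])
        b = make_signature([f"b{i}" for i in range(8)])
        assert so.running_fisher(a, b, 100) == 1.0

    def test_empty_signature_gives_p_one_with_warning(self):
        a = make_signature([])
        b = make_signature(["g1"])
        with pytest.warns(UserWarning, match="empty"):
            assert so.running_fisher(a, b, 100) == 1.0

    def test_small_background_rejected(self):
        a = make_signature([f"a{i}" for i in range(8)])
        b = make_signature([f"b{i}" for i in range(8)])
        with pytest.raises(ValueError, match="background"):
            so.running_fisher(a, b, 10)

    def test_twelve_gene_toy_equals_exhaustive_brute_force(self, rng):
        genes = [f"g{i}" for i in range(12)]
        a = make_signature(genes, p_values=list(rng.uniform(1e-6, 0.05, 12)))
        b = make_signature(list(rng.choice(genes, 5, replace=False)) + ["x1", "x2"])
        bg = 60
        # brute force: every rank as a cutoff, direct tail sums, min times 12
        b_set = b.gene_set
        ps = []
        for k in range(1, 13):
            hits = len(set(list(a.genes)[:k]) & b_set)
            ps.append(_pmf_sum_oracle(hits, k, len(b), bg))
        expected = min(min(ps) * 12, Fraction(1))
        assert so.running_fisher(a, b, bg) == float(expected)

    def test_top_loaded_reference_beats_single_cutoff_test(self, rng):
        """Concentrating the shared genes at the top ranks drives the scan P
        below the whole-list hypergeometric."""
        n_a, bg = 50, 500
        genes = [f"g{i}" for i in range(n_a)]
        a = make_signature(genes, p_values=sorted(rng.uniform(1e-6, 0.05, n_a)))
        top_decile = list(a.genes)[:5]
        b = make_signature(top_decile)
        single = so.hypergeom_upper(5, n_a, len(b), bg)
        assert so.running_fisher(a, b, bg) < single

    def test_adding_rank_one_shared_gene_never_hurts(self, rng):
        """Monotonicity of the scan in the top-ranked shared gene."""
        genes = [f"g{i}" for i in range(20)]
        shared = genes[5:10]
        a = make_signature(genes, p_values=sorted(rng.uniform(1e-4, 0.05, 20)))
        b = make_signature(shared + ["x1", "x2", "x3"])
        before = so.running_fisher(a, b, 200)
        # prepend a new shared gene at rank 1 of A
        a2 = make_signature(["top"] + genes,
                            p_values=[1e-9] + sorted(rng.uniform(1e-4, 0.05, 20)))
        b2 = make_signature(["top"] + shared + ["x1", "x2", "x3"])
        after = so.running_fisher(a2, b2, 200)
        assert after <= before


class TestQuadrants:
    def test_disjoint_signatures_have_empty_quadrants(self):
        a = make_signature(["a1", "a2"], ["up", "down"])
        b = make_signature(["b1", "b2"], ["up", "down"])
        assert so.quadrant_partition(a, b).as_tuple() == (0, 0, 0, 0)

    def test_six_gene_toy_matches_manual_enumeration(self):
        a = make_signature(["g1", "g2", "g3", "g4", "g5", "g6"],
                           ["up", "up", "down", "down", "up", "down"])
        b = make_signature(["g1", "g2", "g3", "g4", "g7", "g8"],
                           ["up", "down", "down", "up", "up", "down"])
        quad = so.quadrant_partition(a, b)
        assert quad.as_tuple() == (1, 1, 1, 1)  # g1 uu, g3 dd, g2 ud, g4 du
        assert quad.genes["uu"] == ("g1",)
        assert quad.genes["du"] == ("g4",)

    def test_swapping_inputs_transposes_ud_and_du(self, rng):
        genes = [f"g{i}" for i in range(30)]
        da = list(rng.choice(["up", "down"], 30))
        db = list(rng.choice(["up", "down"], 30))
        a = make_signature(genes[:20], da[:20])
        b = make_signature(genes[8:], db[8:])
        q1 = so.quadrant_partition(a, b)
        q2 = so.quadrant_partition(b, a)
        assert (q1.uu, q1.dd, q1.ud, q1.du) == (q2.uu, q2.dd, q2.du, q2.ud)

    def test_partition_sums_reproduce_published_overlap(self):
        """Quadrant counts 91/563/193/39 partition an 886-gene overlap with
        654 positive-correlation genes."""
        quads = {"uu": 91, "dd": 563, "ud": 193, "du": 39}
        genes_a, dirs_a, genes_b, dirs_b = [], [], [], []
        i = 0
        for q, n in quads.items():
            for _ in range(n):
                g = f"g{i}"
                i += 1
                genes_a.append(g)
                dirs_a.append("up" if q[0] == "u" else "down")
                genes_b.append(g)
                dirs_b.append("up" if q[1] == "u" else "down")
        a = make_signature(genes_a, dirs_a, background_n=20000)
        b = make_signature(genes_b, dirs_b, background_n=20000)
        quad = so.quadrant_partition(a, b)
        assert quad.as_tuple() == (91, 563, 193, 39)
        assert quad.overlap == 886
        assert quad.concordant == 654


class TestConcordanceChiSquare:
    @pytest.mark.parametrize("conc,disc,expected", [(654, 232, 201.00), (57, 11, 31.12)])
    def test_published_statistics_recompute_exactly(self, conc, disc, expected):
        chi2, p = so.concordance_chi_square(conc, disc)
        assert round(chi2, 2) == expected
        assert 0 < p < 1e-7

    def test_even_split_gives_zero_statistic(self):
        chi2, p = so.concordance_chi_square(50, 50)
        assert chi2 == 0.0 and p == 1.0

    def test_symmetric_in_its_arguments(self):
        assert so.concordance_chi_square(30, 70) == so.concordance_chi_square(70, 30)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            so.concordance_chi_square(0, 0)


class TestDirectionalOverlap:
    def test_empty_direction_subsets_give_p_one(self):
        a = make_signature(["g1", "g2"], ["up", "up"])
        b = make_signature(["g1", "g2"], ["up", "up"])
        with pytest.warns(UserWarning, match="empty"):
            assert so.directional_overlap_p(a, b, "down", "down", 100) == 1.0

    def test_concordant_pair_separates_matched_from_crossed(self):
        cfg = so.SyntheticConfig(n_genes=1000, concordance=1.0, effect_size=2.0,
                                 noise_sd=0.3, seed=21)
        mat_a, mat_b, _ = so.generate_paired_studies(cfg)
        a, b = so.extract_signature(mat_a), so.extract_signature(mat_b)
        bg = 1000
        p_uu = so.directional_overlap_p(a, b, "up", "up", bg)
        p_dd = so.directional_overlap_p(a, b, "down", "down", bg)
        p_ud = so.directional_overlap_p(a, b, "up", "down", bg)
        p_du = so.directional_overlap_p(a, b, "down", "up", bg)
        assert max(p_uu, p_dd) < 1e-10
        assert min(p_ud, p_du) > 0.5


class TestBonferroniLedger:
    def test_single_pair_keeps_printed_levels(self):
        assert so.bonferroni_ledger(1) == (0.05, 0.0125)

    def test_five_pairs_divide_the_pairwise_level(self):
        assert so.bonferroni_ledger(5) == (0.01, 0.0125)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            so.bonferroni_ledger(0)


class TestBackgroundRestriction:
    def test_identical_backgrounds_are_a_noop(self):
        genes = ["g1", "g2", "g3"]
        a = make_signature(genes, ["up", "down", "up"])
        bg = genes + ["g4", "g5"]
        a2, _, n = so.restrict_to_background(a, a, bg)
        assert a2.gene_set == a.gene_set and n == 5

    def test_genes_outside_background_are_dropped(self):
        a = make_signature(["g1", "g2"], ["up", "down"])
        b = make_signature(["g2", "g3"], ["up", "down"])
        with pytest.warns(UserWarning, match="dropped"):
            a2, b2, n = so.restrict_to_background(a, b, ["g1", "g2", "g4"])
        assert a2.gene_set == {"g1", "g2"}
        assert b2.gene_set == {"g2"}
        assert n == 3

    def test_counts_match_brute_force_set_intersection(self, rng):
        universe = [f"g{i}" for i in range(50)]
        a_genes = list(rng.choice(universe, 20, replace=False))
        b_genes = list(rng.choice(universe, 25, replace=False))
        bg = list(rng.choice(universe, 40, replace=False))
        a = make_signature(a_genes)
        b = make_signature(b_genes)
        with pytest.warns(UserWarning):
            a2, b2, n = so.restrict_to_background(a, b, bg)
        assert a2.gene_set == set(a_genes) & set(bg)
        assert b2.gene_set == set(b_genes) & set(bg)

    def test_empty_background_rejected(self):
        a = make_signature(["g1"])
        with pytest.raises(ValueError):
            so.restrict_to_background(a, a, [])


class TestNullCalibration:
    def test_running_fisher_is_conservative_under_independence(self, rng):
        """Independent random signatures reject at most nominally at 0.05."""
        n_sims, rejections = 150, 0
        universe = np.array([f"g{i}" for i in range(800)])
        for _ in range(n_sims):
            a = make_signature(rng.choice(universe, 60, replace=False),
                               p_values=list(rng.uniform(1e-6, 0.05, 60)))
            b = make_signature(rng.choice(universe, 60, replace=False),
                               p_values=list(rng.uniform(1e-6, 0.05, 60)))
            rejections += so.running_fisher(a, b, 800) < 0.05
        mc_se = math.sqrt(0.05 * 0.95 / n_sims)
        assert rejections / n_sims <= 0.05 + 2 * mc_se
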