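"""Synteny classification, hypergeometric tests, length-adjusted nulls,
tRNA association and flanking-gene orientation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, hypergeom

from oriscout.conservation import (
    HomologyTable,
    find_syntenic_pairs,
    flanking_orientation,
    hypergeom_two_sided,
    length_adjusted_test,
    trna_association,
)
from oriscout.genome_io import Feature, IntergenicRegion


def _genes(layout, species="A"):
    """layout: list per chromosome of (name, strand) tuples."""
    feats = []
    for ci, order in enumerate(layout):
        pos = 100
        for name, strand in order:
            feats.append(Feature(f"{species}c{ci + 1}", pos, pos + 500,
                                 strand, "gene", name))
            pos += 800
    return feats


def _identity_homology(names):
    return HomologyTable(pd.DataFrame(
        {"gene_a": names, "gene_b": names, "evalue": 1e-30}))


class TestSynteny:
    def test_identical_layout_all_syntenic(self):
        layout = [[("g1", "+"), ("g2", "-"), ("g3", "+")]]
        a, b = _genes(layout, "A"), _genes(layout, "B")
        hom = _identity_homology(["g1", "g2", "g3"])
        matches, asg_a, asg_b = find_syntenic_pairs(a, b, hom)
        assert len(matches) == 2
        assert asg_a.n_syntenic == 2 and asg_b.n_syntenic == 2

    def test_strand_flip_breaks_orientation(self):
        layout = [[("g1", "+"), ("g2", "-"), ("g3", "+")]]
        a = _genes(layout, "A")
        flipped = [[("g1", "+"), ("g2", "+"), ("g3", "+")]]
        b = _genes(flipped, "B")
        hom = _identity_homology(["g1", "g2", "g3"])
        matches, asg_a, _ = find_syntenic_pairs(a, b, hom)
        assert asg_a.n_syntenic == 0

    def test_whole_pair_inversion_stays_syntenic(self):
        """Adjacency read from the other strand is the same locus."""
        a = _genes([[("g1", "+"), ("g2", "-")]], "A")
        b = _genes([[("g2", "+"), ("g1", "-")]], "B")
        hom = _identity_homology(["g1", "g2"])
        matches, asg_a, _ = find_syntenic_pairs(a, b, hom)
        assert asg_a.n_syntenic == 1

    def test_empty_homology_no_synteny(self):
        layout = [[("g1", "+"), ("g2", "-")]]
        a, b = _genes(layout, "A"), _genes(layout, "B")
        hom = HomologyTable(pd.DataFrame(
            {"gene_a": [], "gene_b": [], "evalue": []}))
        matches, asg_a, _ = find_syntenic_pairs(a, b, hom)
        assert matches == [] and asg_a.n_syntenic == 0

    def test_species_swap_symmetry(self):
        from oriscout.synthetic import SyntenySimConfig, make_synteny_scenario

        sc = make_synteny_scenario(SyntenySimConfig(n_genes=60,
                                                    n_rearrangements=6, seed=3))
        hom_rev = HomologyTable(sc.homology.rename(
            columns={"gene_a": "gene_b", "gene_b": "gene_a"}))
        m_ab, asg_a, asg_b = find_syntenic_pairs(sc.genes_a, sc.genes_b,
                                                 HomologyTable(sc.homology))
        m_ba, asg_b2, asg_a2 = find_syntenic_pairs(sc.genes_b, sc.genes_a,
                                                   hom_rev)
        assert asg_a.syntenic_pairs == asg_a2.syntenic_pairs
        assert asg_b.syntenic_pairs == asg_b2.syntenic_pairs

    def test_unordered_gene_list_error(self):
        a = [Feature("c1", 500, 900, "+", "gene", "g2"),
             Feature("c1", 0, 400, "+", "gene", "g1")]
        with pytest.raises(ValueError, match="ordered"):
            find_syntenic_pairs(a, a, _identity_homology(["g1", "g2"]))


class TestHypergeomTwoSided:
    def test_printed_contingency_values(self):
        """The three published intergene/ARS contingency tables."""
        assert hypergeom_two_sided(5736, 1992, 294, 51) == pytest.approx(
            2.0e-11, rel=0.05)
        assert hypergeom_two_sided(5165, 1988, 145, 37) == pytest.approx(
            0.001, abs=2e-4)
        assert hypergeom_two_sided(1992, 51, 38, 2) == pytest.approx(
            0.51, abs=0.005)

    def test_doubling_convention_pinned_against_min_likelihood(self):
        """Doubling gives 0.51 where the minimum-likelihood convention
        gives ~0.25; the printed value pins doubling."""
        N, K, n, k = 1992, 51, 38, 2
        p_double = hypergeom_two_sided(N, K, n, k)
        pk = hypergeom.pmf(k, N, K, n)
        p_minlik = sum(hypergeom.pmf(i, N, K, n)
                       for i in range(min(K, n) + 1)
                       if hypergeom.pmf(i, N, K, n) <= pk + 1e-15)
        assert p_double == pytest.approx(0.51, abs=0.005)
        assert p_minlik == pytest.approx(0.25, abs=0.01)

    def test_modal_observation_capped_at_one(self):
        N, K, n = 100, 40, 20
        k = round(n * K / N)
        assert hypergeom_two_sided(N, K, n, k) == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_brute_force_pmf_summation(self, data):
        N = data.draw(st.integers(1, 200))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        kmin, kmax = max(0, n - (N - K)), min(K, n)
        k = data.draw(st.integers(kmin, kmax))
        got = hypergeom_two_sided(N, K, n, k)
        pmf = [hypergeom.pmf(i, N, K, n) for i in range(kmin, kmax + 1)]
        lower = sum(p for i, p in zip(range(kmin, kmax + 1), pmf) if i <= k)
        upper = sum(p for i, p in zip(range(kmin, kmax + 1), pmf) if i >= k)
        assert got == pytest.approx(min(1.0, 2 * min(lower, upper)), abs=1e-9)

    def test_bound_violations_error(self):
        with pytest.raises(ValueError):
            hypergeom_two_sided(10, 12, 5, 1)
        with pytest.raises(ValueError):
            hypergeom_two_sided(10, 5, 5, 6)


class TestLengthAdjusted:
    def test_equal_lengths_reduce_to_exact_binomial(self):
        """With equal intergene lengths the MC null is binomial placement;
        the MC p matches the exact doubled binomial p within MC error."""
        N, K, n, k = 40, 10, 12, 6
        lengths = np.full(N, 500.0)
        marked = np.zeros(N, bool)
        marked[:K] = True
        n_draws = 100_000
        p_mc = length_adjusted_test(lengths, marked, n, k, n_draws=n_draws,
                                    seed=3)
        p_exact = min(1.0, 2 * min(binom.cdf(k, n, K / N),
                                   binom.sf(k - 1, n, K / N)))
        se = 2 * np.sqrt(p_exact / 2 * (1 - p_exact / 2) / n_draws)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / n_draws

    def test_brute_force_two_ars_ten_intergenes(self):
        """Enumerating all 100 equally-weighted placements of 2 ARSs in 10
        intergenes gives the exact null; MC agrees within 3 SE."""
        lengths = np.full(10, 100.0)
        marked = np.array([True] * 3 + [False] * 7)
        k_obs = 2
        # exact: k ~ Binomial(2, 0.3) by enumeration of 10*10 placements
        probs = {0: 49 / 100, 1: 42 / 100, 2: 9 / 100}
        lower = probs[0] + probs[1] + probs[2]
        upper = probs[2]
        p_exact = min(1.0, 2 * min(lower, upper))
        p_mc = length_adjusted_test(lengths, marked, 2, k_obs,
                                    n_draws=100_000, seed=9)
        se = np.sqrt(upper * (1 - upper) / 100_000)
        assert abs(p_mc - p_exact) <= 6 * se + 2 / 100_000

    def test_tiny_marked_lengths_give_p_one_at_k_zero(self):
        lengths = np.array([1e-6, 1e-6, 1000.0, 1000.0])
        marked = np.array([True, True, False, False])
        p = length_adjusted_test(lengths, marked, 5, 0, n_draws=2_000, seed=0)
        assert p == 1.0

    def test_reproducible_given_seed(self):
        lengths = np.linspace(100, 1000, 20)
        marked = np.arange(20) % 3 == 0
        a = length_adjusted_test(lengths, marked, 10, 4, 5_000, seed=7)
        b = length_adjusted_test(lengths, marked, 10, 4, 5_000, seed=7)
        assert a == b

    def test_positive_length_required(self):
        with pytest.raises(ValueError):
            length_adjusted_test([100.0, 0.0], [True, False], 2, 1)


class TestTrnaAssociation:
    def _regions(self, n, trna_idx, lengths=None):
        out = []
        for i in range(n):
            r = IntergenicRegion("c1", i * 1000,
                                 i * 1000 + (lengths[i] if lengths else 400))
            r.contains_trna = i in trna_idx
            out.append(r)
        return out

    def test_planting_only_in_trna_intergenes_is_significant(self):
        regions = self._regions(60, set(range(8)))
        ars = [regions[i].region_id for i in range(8)]
        res = trna_association(regions, ars)
        assert res.p_two_sided < 0.05
        assert (res.n_population, res.k_marked, res.n_sample,
                res.k_observed) == (60, 8, 8, 8)

    def test_length_bias_mechanism(self):
        """ARSs placed proportionally to length while tRNA intergenes are
        long: the unadjusted test rejects, the adjusted one does not
        (averaged over seeds)."""
        rng = np.random.default_rng(21)
        n = 120
        trna_idx = set(range(15))
        lengths = [3000 if i in trna_idx else 300 for i in range(n)]
        regions = self._regions(n, trna_idx, lengths)
        p_unadj, p_adj = [], []
        for seed in range(10):
            r = np.random.default_rng((seed, 5))
            probs = np.array(lengths) / np.sum(lengths)
            placements = r.choice(n, size=40, p=probs)
            ars = [regions[i].region_id for i in placements]
            res = trna_association(regions, ars, adjust_length=True,
                                   n_draws=20_000, seed=seed)
            p_unadj.append(res.p_two_sided)
            p_adj.append(res.p_length_adjusted)
        assert np.median(p_unadj) < 0.01
        assert np.median(p_adj) > 0.1

    def test_no_trna_intergenes_k_zero(self):
        regions = self._regions(10, set())
        res = trna_association(regions, [])
        assert res.k_marked == 0 and res.p_two_sided == 1.0


class TestFlankingOrientation:
    def _region(self, ls, rs, start=100, end=200):
        return IntergenicRegion(
            "c1", start, end,
            left_gene=Feature("c1", start - 50, start, ls, "gene", "L"),
            right_gene=Feature("c1", end, end + 50, rs, "gene", "R"))

    def test_convergent_divergent_tandem(self):
        regions = [self._region("+", "-", 100, 200),
                   self._region("-", "+", 300, 400),
                   self._region("+", "+", 500, 600),
                   self._region("-", "-", 700, 800)]
        counts = flanking_orientation(
            [("c1", 150), ("c1", 350), ("c1", 550), ("c1", 750)], regions)
        assert (counts.fr, counts.rf, counts.ffrr) == (1, 1, 2)
        assert counts.n_ars == 4

    def test_terminal_intergenes_skipped_and_counted(self):
        terminal = IntergenicRegion("c1", 0, 100, left_gene=None,
                                    right_gene=Feature("c1", 100, 150, "+",
                                                       "gene", "R"))
        counts = flanking_orientation([("c1", 50)], [terminal])
        assert counts.n_ars == 0 and counts.n_skipped_terminal == 1

    def test_random_strands_near_expected_proportions(self):
        """Random flanking strands give 1/4, 1/4, 1/2 within binomial
        error."""
        rng = np.random.default_rng(13)
        n = 600
        regions, centers = [], []
        for i in range(n):
            ls, rs = rng.choice(["+", "-"], 2)
            regions.append(self._region(ls, rs, 1000 * i + 100, 1000 * i + 200))
            centers.append(("c1", 1000 * i + 150))
        counts = flanking_orientation(centers, regions)
        se = 3 * np.sqrt(0.25 * 0.75 / n)
        assert abs(counts.fr / n - 0.25) < se
        assert abs(counts.rf / n - 0.25) < se
        assert abs(counts.ffrr / n - 0.5) < 3 * np.sqrt(0.5 * 0.5 / n)
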