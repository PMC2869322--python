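"""Window scoring, exact-DP thresholds, scanning, gapped scanning and
candidate ranking."""

from itertools import product

import numpy as np
import pytest

from oriscout.genome_io import CandidateRecord, IntergenicRegion, RegionMask, Site
from oriscout.motif import MarkovBackground, PWM, fit_markov
from oriscout.scanner import (
    GRID,
    SiteScorer,
    _null_distribution_dp,
    best_match,
    gapped_scan,
    learn_threshold,
    rank_candidates,
    scan_regions,
    site_score,
)
from oriscout._seq import encode, revcomp_codes


def _random_pwm(rng, w, conc=1.0):
    probs = rng.dirichlet(np.ones(4) * conc, size=w)
    probs = np.clip(probs, 1e-4, None)
    return PWM(probs / probs.sum(axis=1, keepdims=True))


def _random_bg(rng, order):
    cond = rng.dirichlet(np.ones(4) * 2, size=4**order)
    cond = np.clip(cond, 1e-3, None)
    return MarkovBackground(cond / cond.sum(axis=1, keepdims=True), order)


def _exact_window_prob(bg, x):
    """Stationary-chain probability of a window; independent of scorer."""
    m = bg.order
    if m == 0:
        p = 1.0
        for b in x:
            p *= bg.cond[0, b]
        return p
    c = 0
    for j in range(m):
        c = (c << 2) | int(x[j])
    p = bg.pi[c]
    for k in range(m, len(x)):
        p *= bg.cond[c, x[k]]
        c = ((c << 2) | int(x[k])) & (4**m - 1)
    return p


class TestSiteScore:
    def test_pwm_equal_to_background_scores_zero(self, uniform_bg):
        pwm = PWM(np.full((4, 4), 0.25))
        assert site_score(pwm, uniform_bg, "ACGT") == 0.0

    def test_hand_computed_likelihood_ratio(self, uniform_bg):
        """w=2 PWM vs uniform null: log2(0.49/0.0625) = 2.971, reproduced
        to within the per-column discretization bound."""
        pwm = PWM(np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]]))
        s = site_score(pwm, uniform_bg, "AC")
        assert abs(s - np.log2(0.49 / 0.0625)) <= 2 * GRID / 2 + GRID

    def test_window_with_n_skipped(self, uniform_bg):
        pwm = PWM(np.full((3, 4), 0.25))
        assert site_score(pwm, uniform_bg, "ANG") is None

    def test_discretization_error_bound(self):
        """|discretized - exact| <= w * grid/2 per site (both strands)."""
        rng = np.random.default_rng(3)
        w = 6
        bg = _random_bg(rng, 1)
        pwm = _random_pwm(rng, w)
        sc = SiteScorer(pwm, bg)
        for _ in range(50):
            x = rng.integers(0, 4, w).astype(np.int8)
            pf = _exact_window_prob(bg, x)
            pr = _exact_window_prob(bg, revcomp_codes(x))
            ppwm = np.prod([pwm.probs[j, x[j]] for j in range(w)])
            exact = np.log2(ppwm / ((pf + pr) / 2))
            got = sc.score_window(x, "+")
            # elementary terms: w pwm + (1 + w - m) per strand-likelihood
            n_terms = w + 2 * (1 + w - bg.order) + 1
            assert abs(got - exact) <= n_terms * GRID / 2 + GRID


class TestLearnThreshold:
    @pytest.mark.parametrize("order,w", [
        (0, 2), (0, 3), (0, 5), (1, 2), (1, 3), (1, 5), (2, 3), (2, 4), (2, 5)])
    def test_dp_equals_enumeration(self, order, w):
        """The DP null distribution equals brute-force enumeration over
        all 4^w windows, exactly."""
        rng = np.random.default_rng(order * 10 + w)
        bg = _random_bg(rng, order)
        pwm = _random_pwm(rng, w)
        sc = SiteScorer(pwm, bg)
        dist = {}
        for wnd in product(range(4), repeat=w):
            x = np.array(wnd, dtype=np.int8)
            s = sc.score_window(x, "+")
            dist[s] = dist.get(s, 0.0) + _exact_window_prob(bg, x)
        scores, probs = _null_distribution_dp(sc, 10**7)
        want = np.array(sorted(dist))
        assert np.allclose(scores, want)
        assert np.allclose(probs, [dist[s] for s in want], atol=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pvalue_one_gives_minimum_score(self, uniform_bg):
        pwm = PWM(np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]]))
        thr = learn_threshold(pwm, uniform_bg, 1.0)
        scores, _ = _null_distribution_dp(SiteScorer(pwm, uniform_bg), 10**6)
        assert thr.cutoff == scores.min()

    def test_threshold_is_minimal_on_grid(self):
        rng = np.random.default_rng(4)
        bg = _random_bg(rng, 1)
        pwm = _random_pwm(rng, 4, conc=0.5)
        thr = learn_threshold(pwm, bg, 0.05)
        assert thr.tail_at(thr.cutoff) <= 0.05
        below = thr.scores[thr.scores < thr.cutoff - 1e-9]
        if below.size:
            assert thr.tail_at(float(below[-1])) > 0.05

    def test_invalid_pvalue(self, uniform_bg):
        pwm = PWM(np.full((2, 4), 0.25))
        with pytest.raises(ValueError):
            learn_threshold(pwm, uniform_bg, 0.0)

    def test_monte_carlo_agrees_with_dp(self):
        rng = np.random.default_rng(5)
        bg = _random_bg(rng, 1)
        pwm = _random_pwm(rng, 4)
        dp = learn_threshold(pwm, bg, 0.05, method="exact-DP")
        mc = learn_threshold(pwm, bg, 0.05, method="monte-carlo",
                             mc_draws=200_000, seed=8)
        assert abs(dp.cutoff - mc.cutoff) <= 0.25


class TestScanRegions:
    def test_planted_sites_all_recovered(self, small_sim):
        genome, truth = small_sim.genome, small_sim.truth
        bg = fit_markov(small_sim.intergenic_sequences(), order=2)
        thr = learn_threshold(truth.pwm, bg, 1e-4, method="monte-carlo",
                              mc_draws=50_000, seed=0)
        hits = scan_regions(truth.pwm, bg, truth.intergenes, genome,
                            threshold=thr)
        starts = {(h.chrom, h.start) for h in hits}
        planted = [s for s in truth.sites]
        found = sum((s.chrom, s.start) in starts for s in planted)
        assert found == len(planted)

    def test_mask_removes_exactly_masked_hits(self, small_sim):
        genome, truth = small_sim.genome, small_sim.truth
        bg = fit_markov(small_sim.intergenic_sequences(), order=2)
        thr = learn_threshold(truth.pwm, bg, 1e-4, method="monte-carlo",
                              mc_draws=50_000, seed=0)
        site = truth.sites[0]
        mask = RegionMask([(site.chrom, site.start, site.end)])
        free = scan_regions(truth.pwm, bg, truth.intergenes, genome, thr)
        masked = scan_regions(truth.pwm, bg, truth.intergenes, genome, thr,
                              mask=mask)
        dropped = {(h.chrom, h.start, h.strand) for h in free} - {
            (h.chrom, h.start, h.strand) for h in masked}
        assert dropped
        assert all(mask.overlaps(c, s, s + truth.pwm.width)
                   for c, s, _ in dropped)

    def test_region_shorter_than_motif(self, uniform_bg, make_genome):
        genome = make_genome({"c1": "ACGTACGT"})
        pwm = PWM(np.full((10, 4), 0.25))
        region = IntergenicRegion("c1", 0, 8)
        assert scan_regions(pwm, uniform_bg, [region], genome) == []
        assert best_match(pwm, uniform_bg, region, genome) is None

    def test_lower_pvalue_never_adds_hits(self, small_sim):
        genome, truth = small_sim.genome, small_sim.truth
        bg = fit_markov(small_sim.intergenic_sequences(), order=2)
        regions = truth.intergenes[:40]
        loose = learn_threshold(truth.pwm, bg, 1e-3, method="monte-carlo",
                                mc_draws=50_000, seed=1)
        tight = learn_threshold(truth.pwm, bg, 1e-5, method="monte-carlo",
                                mc_draws=50_000, seed=1)
        h_loose = {(h.chrom, h.start, h.strand)
                   for h in scan_regions(truth.pwm, bg, regions, genome, loose)}
        h_tight = {(h.chrom, h.start, h.strand)
                   for h in scan_regions(truth.pwm, bg, regions, genome, tight)}
        assert h_tight <= h_loose


class TestBestMatch:
    def test_consensus_padded_by_background(self, uniform_bg, make_genome):
        consensus = "ACTT"
        probs = np.full((4, 4), 0.04)
        for j, b in enumerate(consensus):
            probs[j, "ACGT".index(b)] = 0.88
        pwm = PWM(probs)
        genome = make_genome({"c1": "GGGGG" + consensus + "GGGGG"})
        region = IntergenicRegion("c1", 0, 14)
        hit = best_match(pwm, uniform_bg, region, genome)
        assert hit.start == 5 and hit.strand == "+"

    def test_tie_breaks_to_lower_start(self, uniform_bg, make_genome):
        pwm = PWM(np.array([[0.97, 0.01, 0.01, 0.01],
                            [0.97, 0.01, 0.01, 0.01]]))
        genome = make_genome({"c1": "AAGGAA"})
        hit = best_match(pwm, uniform_bg, IntergenicRegion("c1", 0, 6), genome)
        assert hit.start == 0

    def test_strand_symmetric_scores(self, uniform_bg, make_genome):
        rng = np.random.default_rng(6)
        pwm = _random_pwm(rng, 5, conc=0.4)
        seq = "".join(rng.choice(list("ACGT"), 60))
        from oriscout._seq import revcomp

        g1 = make_genome({"c1": seq})
        g2 = make_genome({"c1": revcomp(seq)})
        r = IntergenicRegion("c1", 0, 60)
        h1 = best_match(pwm, uniform_bg, r, g1)
        h2 = best_match(pwm, uniform_bg, r, g2)
        assert h1.score == h2.score

    def test_best_match_centers_on_planted(self, small_sim):
        genome, truth = small_sim.genome, small_sim.truth
        bg = fit_markov(small_sim.intergenic_sequences(), order=2)
        planted_regions = []
        for s in truth.sites:
            for r in truth.intergenes:
                if r.chrom == s.chrom and r.start <= s.start and s.end <= r.end:
                    planted_regions.append((s, r))
                    break
        ok = 0
        for s, r in planted_regions:
            hit = best_match(truth.pwm, bg, r, genome)
            ok += s.start <= hit.center < s.end
        assert ok / len(planted_regions) >= 0.99


class TestGappedScan:
    def test_gap_zero_reduces_to_ungapped(self, small_sim):
        genome, truth = small_sim.genome, small_sim.truth
        bg = fit_markov(small_sim.intergenic_sequences(), order=2)
        regions = truth.intergenes[:5]
        plain = scan_regions(truth.pwm, bg, regions, genome, threshold=5.0)
        gapped = gapped_scan(truth.pwm, bg, regions, genome, gap_position=25,
                             gap_lengths=(0,), threshold=5.0)
        assert {(h.chrom, h.start, h.strand, h.score) for h in plain} == {
            (h.chrom, h.start, h.strand, h.score) for h in gapped}

    def test_insertion_construct_recovered_by_gapped_scan(self, uniform_bg,
                                                          make_genome):
        """A motif with 2 bases inserted mid-motif scores poorly ungapped
        but recovers the intact-motif score with g=2."""
        rng = np.random.default_rng(8)
        w = 12
        consensus = "TTTAGCGCTAAA"
        probs = np.full((w, 4), 0.03)
        for j, b in enumerate(consensus):
            probs[j, "ACGT".index(b)] = 0.91
        pwm = PWM(probs)
        gp = 6
        broken = consensus[:gp] + "GG" + consensus[gp:]
        seq = "ACGTACGTAC" + broken + "GTACGTACGT"
        genome = make_genome({"c1": seq})
        region = IntergenicRegion("c1", 0, len(seq))
        intact_score = site_score(pwm, uniform_bg, consensus)
        plain = best_match(pwm, uniform_bg, region, genome)
        hits = gapped_scan(pwm, uniform_bg, [region], genome, gap_position=gp,
                           gap_lengths=(2,), threshold=intact_score - 1.0)
        assert plain.score < intact_score - 3
        assert any(h.gap == (gp, 2) for h in hits)
        best = max(h.score for h in hits)
        # null is on the w+2 window, so scores differ slightly from intact
        assert best >= intact_score - 1.0

    def test_brute_force_deletion_placements(self, uniform_bg, make_genome):
        """w=4, g=1 on a 10 bp region equals hand enumeration of deletion
        placements."""
        rng = np.random.default_rng(9)
        pwm = _random_pwm(rng, 4, conc=0.6)
        seq = "ACGGTTACGT"
        genome = make_genome({"c1": seq})
        region = IntergenicRegion("c1", 0, 10)
        gp = 2
        hits = gapped_scan(pwm, uniform_bg, [region], genome, gap_position=gp,
                           gap_lengths=(1,))
        sc = SiteScorer(pwm, uniform_bg)
        arr = encode(seq)
        for h in [h for h in hits if h.strand == "+"]:
            win = arr[h.start:h.end]  # length 5
            deleted = np.concatenate([win[:gp], win[gp + 1:]])
            U = sum(int(sc.rtheta[j, deleted[j]]) for j in range(4))
            U -= sc._full_ll(win)
            W = sc._full_ll(revcomp_codes(win)) - sc._full_ll(win)
            assert h.score == float(sc._final(U, W))

    def test_gap_position_validation(self, uniform_bg, make_genome):
        pwm = PWM(np.full((4, 4), 0.25))
        genome = make_genome({"c1": "ACGTACGT"})
        with pytest.raises(ValueError):
            gapped_scan(pwm, uniform_bg, [IntergenicRegion("c1", 0, 8)],
                        genome, gap_position=0)


class TestRankCandidates:
    def _mk_hits(self, scores):
        from oriscout.scanner import ScanHit

        hits, regions = [], []
        for i, s in enumerate(scores):
            start = i * 100
            regions.append(IntergenicRegion("c1", start, start + 90))
            hits.append(ScanHit("c1", start + 10, start + 20, "+", s,
                                region_id=f"c1:{start}-{start + 90}"))
        return hits, regions

    def test_tie_extends_batch(self):
        scores = [25.0 - i for i in range(18)] + [6.5, 6.5, 6.5, 5.0, 4.0, 3.0, 2.0]
        hits, regions = self._mk_hits(scores)
        batch = rank_candidates(hits, regions, batch_target=20)
        assert len(batch) == 21
        assert batch[-1].score == 6.5

    def test_overlap_with_verified_excluded(self):
        hits, regions = self._mk_hits([9.0, 8.0, 7.0])
        verified = [Site("c1", 12, 22, strand="+")]  # overlaps first hit
        batch = rank_candidates(hits, regions, prior_verified=verified,
                                batch_target=5)
        assert all(c.acs_start != 10 for c in batch)
        assert len(batch) == 2

    def test_coding_hits_flagged_when_admitted(self):
        from oriscout.scanner import ScanHit

        regions = [IntergenicRegion("c1", 0, 90)]
        hits = [ScanHit("c1", 10, 20, "+", 9.0, region_id="c1:0-90"),
                ScanHit("c1", 500, 510, "+", 8.0)]
        only = rank_candidates(hits, regions, batch_target=5)
        both = rank_candidates(hits, regions, batch_target=5,
                               intergenic_only=False)
        assert len(only) == 1
        assert len(both) == 2 and any(c.in_coding for c in both)

    def test_one_candidate_per_intergene(self):
        from oriscout.scanner import ScanHit

        region = IntergenicRegion("c1", 0, 200)
        hits = [ScanHit("c1", 10, 20, "+", 9.0, region_id=region.region_id),
                ScanHit("c1", 100, 110, "+", 8.0, region_id=region.region_id)]
        batch = rank_candidates(hits, [region], batch_target=5)
        assert len(batch) == 1 and batch[0].score == 9.0


class TestColumnMaskAndDesertBonus:
    def test_masking_all_columns_zeroes_the_score(self, uniform_bg):
        pwm = PWM(np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]]))
        mask = np.zeros(2, dtype=bool)
        assert site_score(pwm, uniform_bg, "AC", column_mask=mask) == 0.0

    def test_masked_column_contributes_nothing(self, uniform_bg):
        """Masking one column removes exactly that column's contribution
        (order-0 background: PWM term minus background term)."""
        pwm = PWM(np.array([[0.7, 0.1, 0.1, 0.1],
                            [0.1, 0.7, 0.1, 0.1],
                            [0.25, 0.25, 0.25, 0.25]]))
        full = site_score(pwm, uniform_bg, "ACG")
        mask = np.array([True, False, True])
        masked = site_score(pwm, uniform_bg, "ACG", column_mask=mask)
        contrib = (round(np.log2(0.7), 2) - round(np.log2(0.25), 2))
        assert masked == pytest.approx(full - contrib, abs=1e-9)

    def test_default_mask_drops_weak_columns(self, uniform_bg):
        from oriscout.scanner import default_column_mask

        pwm = PWM(np.array([[0.97, 0.01, 0.01, 0.01],
                            [0.25, 0.25, 0.25, 0.25]]))
        mask = default_column_mask(pwm, uniform_bg)
        assert mask.tolist() == [True, False]

    def test_desert_bonus_prefers_distant_candidates(self):
        from oriscout.scanner import ScanHit

        regions = [IntergenicRegion("c1", i * 1000, i * 1000 + 900)
                   for i in range(3)]
        # equal scores; verified locus sits near the first candidate
        hits = [ScanHit("c1", 100, 150, "+", 8.0, region_id=regions[0].region_id),
                ScanHit("c1", 1100, 1150, "+", 8.0, region_id=regions[1].region_id),
                ScanHit("c1", 2100, 2150, "+", 8.0, region_id=regions[2].region_id)]
        verified = [Site("c1", 300, 350)]
        plain = rank_candidates(hits, regions, prior_verified=verified,
                                batch_target=1)
        boosted = rank_candidates(hits, regions, prior_verified=verified,
                                  batch_target=1, desert_bonus=1.0)
        assert plain[0].acs_start == 100  # tie broken by coordinate
        assert boosted[0].acs_start == 2100  # farthest from verified ARS
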