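"""Estimating the total number of genomic sites from a random screen.

The screen is a uniform random sample of the unknown full repertoire. A
leave-one-out (LOO) procedure estimates the detection rate d(t): each
screened site is held out in turn, the PWM is re-learned from the remaining
sites, and the held-out site counts as detected at threshold t when the
best PWM match inside its intergene lands on the true site (>= 50% window
overlap) and scores >= t. With V(t) verified sites found at or above t
genome-wide, the total repertoire is estimated by inverting the detection
rate, N_hat = V/d(t), and a confidence interval is obtained from exact
binomial (Clopper-Pearson) bounds on d(t):

    L = max(V, ceil(V / d_hi)),    U = ceil(V / d_lo).

V is treated as observed without error (the verification assay is taken as
the gold standard); the LOO rate is slightly pessimistic (it trains on n-1
sites), both of which push the interval upward - conservative against
underestimating the repertoire, the property the coverage simulation
validates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import beta

from .genome_io import Site
from .iterate import training_sequences
from .motif import MarkovBackground, fit_markov, pwm_from_sites
from .scanner import SiteScorer, best_match, learn_threshold, window_overlap_frac

__all__ = [
    "DetectionCurve",
    "CountCI",
    "CoverageReport",
    "loo_detection",
    "clopper_pearson",
    "invert_detection",
    "estimate_total",
    "coverage_simulation",
]


@dataclass
class DetectionCurve:
    """Per-held-out-site LOO outcomes and the induced detection curve."""

    scores: np.ndarray  # best-match score per held-out site (NaN if none)
    localized: np.ndarray  # best match overlapped the true site
    n_screen: int

    def detected_at(self, t: float) -> int:
        ok = self.localized & (np.nan_to_num(self.scores, nan=-np.inf) >= t - 1e-9)
        return int(ok.sum())

    def d(self, t: float) -> float:
        return self.detected_at(t) / self.n_screen

    def thresholds(self) -> np.ndarray:
        s = self.scores[self.localized & np.isfinite(self.scores)]
        return np.unique(s)


@dataclass
class CountCI:
    n_hat: int
    lower: int
    upper: int
    confidence: float
    threshold: float
    v: int
    d_hat: float
    d_lower: float
    d_upper: float
    method: str = "LOO detection-rate inversion with Clopper-Pearson bounds"


@dataclass
class CoverageReport:
    n_reps: int
    miss_low: int
    miss_high: int
    covered: int
    details: list = field(repr=False, default_factory=list)

    @property
    def miss_low_rate(self) -> float:
        return self.miss_low / self.n_reps

    @property
    def miss_high_rate(self) -> float:
        return self.miss_high / self.n_reps

    @property
    def coverage(self) -> float:
        return self.covered / self.n_reps

    def miss_low_se(self) -> float:
        p = self.miss_low_rate
        return math.sqrt(p * (1 - p) / self.n_reps)


def loo_detection(screen_sites, genome, background: MarkovBackground,
                  intergenes, pseudocount: float = 0.01,
                  identity_threshold: float = 0.9,
                  overlap_frac: float = 0.5) -> DetectionCurve:
    """Leave-one-out detection outcomes for a screened site sample.

    Each site must lie in one of the given intergenes (matched by center
    position). Requires at least two sites.
    """
    sites = list(screen_sites)
    if len(sites) < 2:
        raise ValueError("need at least two screened sites")
    regions_by_chrom: dict[str, list] = {}
    for r in intergenes:
        regions_by_chrom.setdefault(r.chrom, []).append(r)
    for lst in regions_by_chrom.values():
        lst.sort(key=lambda r: r.start)

    def region_of(site: Site):
        c = (site.start + site.end) // 2
        for r in regions_by_chrom.get(site.chrom, []):
            if r.start <= c < r.end:
                return r
        raise ValueError(f"site {site} lies in no given intergene")

    regions = [region_of(s) for s in sites]
    scores = np.full(len(sites), np.nan)
    localized = np.zeros(len(sites), dtype=bool)
    for i, site in enumerate(sites):
        rest = sites[:i] + sites[i + 1:]
        seqs, _ = training_sequences(genome, rest, identity_threshold)
        pwm = pwm_from_sites(seqs, pseudocount=pseudocount,
                             provenance=f"LOO holdout {i}")
        scorer = SiteScorer(pwm, background)
        hit = best_match(pwm, background, regions[i], genome, scorer=scorer)
        if hit is None:
            continue
        scores[i] = hit.score
        localized[i] = window_overlap_frac(
            hit.start, hit.end, site.start, site.end) >= overlap_frac
    return DetectionCurve(scores=scores, localized=localized,
                          n_screen=len(sites))


def clopper_pearson(k: int, n: int, confidence: float = 0.95):
    """Exact binomial confidence bounds on a proportion."""
    alpha = 1 - confidence
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def invert_detection(v: int, d_hat: float, d_lo: float, d_hi: float,
                     threshold: float = float("nan"),
                     confidence: float = 0.95) -> CountCI:
    """Turn detection-rate bounds into bounds on the total count."""
    if d_hat <= 0:
        raise ValueError("detection rate is 0 at this threshold; lower it")
    n_hat = max(v, int(round(v / d_hat)))
    lower = max(v, math.ceil(v / d_hi - 1e-9)) if d_hi > 0 else v
    upper = math.ceil(v / d_lo - 1e-9) if d_lo > 0 else int(1e18)
    upper = max(upper, n_hat)
    return CountCI(n_hat=n_hat, lower=lower, upper=upper,
                   confidence=confidence, threshold=threshold, v=v,
                   d_hat=d_hat, d_lower=d_lo, d_upper=d_hi)


def estimate_total(curve: DetectionCurve, v: int, threshold: float,
                   confidence: float = 0.95) -> CountCI:
    """Point estimate and CI for the total site count from the LOO curve
    and the number V of verified sites at/above the threshold."""
    if v <= 0:
        raise ValueError("V must be positive")
    k = curve.detected_at(threshold)
    if k == 0:
        raise ValueError("LOO detection rate is 0 at this threshold")
    d_lo, d_hi = clopper_pearson(k, curve.n_screen, confidence)
    return invert_detection(v, k / curve.n_screen, d_lo, d_hi,
                            threshold=threshold, confidence=confidence)


# ---------------------------------------------------------------------------
# coverage validation on synthetic genomes
# ---------------------------------------------------------------------------


def coverage_simulation(sim_config, n_reps: int, seed: int,
                        screen_size: int = 69, confidence: float = 0.95,
                        pvalue: float = 1e-4, analysis_order: int = 4,
                        mc_draws: int = 100_000) -> CoverageReport:
    """Validate CI coverage: plant a known repertoire, screen a random
    subset, run LOO + estimation, and record whether the interval misses
    the truth from below (the failure mode the method guards against) or
    above.

    V is obtained the way the real study obtains it: scan every intergene
    with the full-screen PWM, keep best matches at/above the threshold, and
    verify them against the (noise-free) truth.
    """
    from .synthetic import generate_genome

    miss_low = miss_high = covered = 0
    details = []
    for rep in range(n_reps):
        ss = np.random.SeedSequence((seed, rep))
        child = [int(x % (2**31)) for x in ss.generate_state(3)]
        cfg = replace(sim_config, seed=child[0])
        sim = generate_genome(cfg)
        genome, truth = sim.genome, sim.truth
        planted_inter = [s for s in truth.sites
                         if _in_regions(s, truth.intergenes)]
        n_true = len(planted_inter)
        rng = np.random.default_rng(child[1])
        idx = rng.choice(len(planted_inter), size=min(screen_size, n_true),
                         replace=False)
        screen = [planted_inter[i] for i in sorted(int(i) for i in idx)]

        bg = fit_markov(sim.intergenic_sequences(), order=analysis_order,
                        trained_on="synthetic intergenes")
        seqs, _ = training_sequences(genome, screen)
        pwm = pwm_from_sites(seqs, provenance="screen PWM")
        thr = learn_threshold(pwm, bg, pvalue, method="auto",
                              mc_draws=mc_draws, seed=child[2])
        curve = loo_detection(screen, genome, bg, truth.intergenes)

        # discover-and-verify V: best hit per intergene at/above threshold
        scorer = SiteScorer(pwm, bg)
        v = 0
        for region in truth.intergenes:
            hit = best_match(pwm, bg, region, genome, scorer=scorer)
            if hit is None or hit.score < thr.cutoff - 1e-9:
                continue
            if any(s.chrom == hit.chrom and window_overlap_frac(
                    hit.start, hit.end, s.start, s.end) >= 0.5
                   for s in planted_inter):
                v += 1
        try:
            ci = estimate_total(curve, v, thr.cutoff, confidence)
        except ValueError:
            details.append({"rep": rep, "error": "zero detection"})
            miss_low += 1  # count degenerate estimation as a failure
            continue
        if ci.upper < n_true:
            miss_low += 1
            outcome = "miss_low"
        elif ci.lower > n_true:
            miss_high += 1
            outcome = "miss_high"
        else:
            covered += 1
            outcome = "covered"
        details.append({"rep": rep, "n_true": n_true, "v": v,
                        "d_hat": ci.d_hat, "ci": (ci.lower, ci.upper),
                        "n_hat": ci.n_hat, "outcome": outcome})
    return CoverageReport(n_reps=n_reps, miss_low=miss_low,
                          miss_high=miss_high, covered=covered,
                          details=details)


def _in_regions(site: Site, regions) -> bool:
    c = (site.start + site.end) // 2
    return any(r.chrom == site.chrom and r.start <= c < r.end for r in regions)
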