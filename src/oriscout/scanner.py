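"""PWM genome scanning against a Markov background with exact p-value
thresholds.

A window x of width w is scored as

    score(x) = log2  P_pwm(x) / Pbar_bg(x),

where Pbar_bg is the arithmetic mean of the background likelihoods of the
window and of its reverse complement (the averaged-strands null; a
per-strand null is available via ``null_mode="per_strand"``). Window
likelihoods start from the stationary m-mer distribution of the background.

Scores are discrete: every elementary log2 quantity (PWM column term,
background conditional, stationary m-mer term) is rounded to a 0.01 grid
before summation. This makes the null score distribution exactly computable
by dynamic programming over Markov contexts: the DP tracks the joint
distribution of the integer pair (U, W), where U is the PWM-versus-forward
grid score and W the reverse-versus-forward grid log-ratio, with
reverse-strand contributions emitted with an m-step delay. When the sparse
state space exceeds a budget (w=50, order 4), threshold learning falls back
to seeded Monte Carlo sampling from the background.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from ._seq import N_CODE, encode, revcomp_codes, rolling_codes
from .genome_io import CandidateRecord, IntergenicRegion, RegionMask
from .motif import PWM, MarkovBackground

GRID = 0.01

__all__ = [
    "GRID",
    "ScanHit",
    "ScoreThreshold",
    "SiteScorer",
    "site_score",
    "learn_threshold",
    "scan_regions",
    "best_match",
    "gapped_scan",
    "rank_candidates",
    "default_column_mask",
]


@dataclass(frozen=True)
class ScanHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    gap: tuple[int, int] | None = None  # (position, length)
    region_id: str = ""

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ScoreThreshold:
    """Score cutoff t* with P_null(score >= t*) <= pvalue, minimal on the
    grid; carries the null tail for sensitivity analyses."""

    pvalue: float
    cutoff: float
    method: str  # "exact-DP" or "monte-carlo"
    scores: np.ndarray  # ascending unique grid scores of the null
    tail: np.ndarray  # P(score >= scores[i])

    def tail_at(self, t: float) -> float:
        i = bisect.bisect_left(list(self.scores), t - 1e-9)
        return float(self.tail[i]) if i < len(self.scores) else 0.0


class _BudgetExceeded(Exception):
    pass


def _rlog2(x: np.ndarray) -> np.ndarray:
    return np.rint(np.log2(x) / GRID).astype(np.int64)


class SiteScorer:
    """Precomputed discretized tables for scoring windows of one PWM
    against one background; shared by scanning, thresholds and the DP."""

    def __init__(self, pwm: PWM, background: MarkovBackground,
                 null_mode: str = "avg_strands",
                 column_mask: np.ndarray | None = None):
        if null_mode not in ("avg_strands", "per_strand"):
            raise ValueError(f"unknown null_mode {null_mode!r}")
        self.pwm = pwm
        self.background = background
        self.null_mode = null_mode
        self.w = pwm.width
        self.m = background.order
        if self.m >= self.w:
            raise ValueError("background order must be < motif width")
        if np.any(pwm.probs <= 0) or np.any(background.cond <= 0):
            raise ValueError("scoring requires strictly positive PWM and "
                             "background probabilities (use a pseudocount)")
        self.rtheta = _rlog2(pwm.probs)  # (w,4)
        self.rcond = _rlog2(background.cond)  # (4^m,4)
        self.rpi = (_rlog2(background.pi) if self.m > 0
                    else np.zeros(1, dtype=np.int64))
        if column_mask is None:
            self.col_use = np.ones(self.w, dtype=bool)
        else:
            self.col_use = np.asarray(column_mask, dtype=bool)
            if self.col_use.shape != (self.w,):
                raise ValueError("column_mask must have one flag per column")
        # reverse-complement PWM table for minus-strand matches
        comp = np.array([3, 2, 1, 0])
        self.rtheta_rc = self.rtheta[::-1][:, comp]
        self.col_use_rc = self.col_use[::-1]

    # -- final score from integer components ------------------------------

    def _final(self, U, W):
        if self.null_mode == "per_strand":
            s = GRID * np.asarray(U, dtype=float)
        else:
            Wf = GRID * np.asarray(W, dtype=float)
            # log2((1 + 2^W)/2) computed stably
            s = GRID * np.asarray(U, dtype=float) - (np.logaddexp2(0.0, Wf) - 1.0)
        return np.round(s, 2)

    # -- single-window scoring (shared by brute-force oracles) ------------

    def components(self, x: np.ndarray) -> tuple[int, int] | None:
        """(U, W) integer grid components of a w-window, or None if it
        contains N."""
        w = self.w
        if len(x) != w:
            raise ValueError(f"window length {len(x)} != {w}")
        if np.any(x == N_CODE):
            return None
        Lf = self._full_ll(x)
        Lr = self._full_ll(revcomp_codes(x))
        U = int(sum(self.rtheta[j, x[j]] for j in range(w) if self.col_use[j]))
        U -= self._masked_ll(x)
        return U, int(Lr - Lf)

    def _full_ll(self, x: np.ndarray) -> int:
        """Grid log2 background likelihood of an arbitrary-length window
        starting from the stationary m-mer distribution."""
        m = self.m
        total = 0
        if m > 0:
            c = 0
            for j in range(m):
                c = (c << 2) | int(x[j])
            total += int(self.rpi[c])
        else:
            c = 0
        mask = (1 << (2 * m)) - 1 if m > 0 else 0
        for k in range(m, len(x)):
            total += int(self.rcond[c, x[k]])
            c = ((c << 2) | int(x[k])) & mask if m > 0 else 0
        return total

    def _masked_ll(self, x: np.ndarray) -> int:
        """Forward-likelihood part entering U: the stationary initial term
        plus the conditionals at unmasked positions >= m."""
        m = self.m
        total = 0
        if m > 0:
            c = 0
            for j in range(m):
                c = (c << 2) | int(x[j])
            total += int(self.rpi[c])
        else:
            c = 0
        mask = (1 << (2 * m)) - 1 if m > 0 else 0
        for k in range(m, len(x)):
            if self.col_use[k] if k < self.w else True:
                total += int(self.rcond[c, x[k]])
            c = ((c << 2) | int(x[k])) & mask if m > 0 else 0
        return total

    def score_window(self, window, strand: str = "+") -> float | None:
        """Score one oriented window (genome-strand sequence; for '-' the
        PWM is matched against its reverse complement). None on N."""
        x = encode(window) if isinstance(window, str) else np.asarray(window, np.int8)
        if np.any(x == N_CODE):
            return None
        Lf = self._full_ll(x)
        Lr = self._full_ll(revcomp_codes(x))
        if strand == "+":
            U = int(sum(self.rtheta[j, x[j]] for j in range(self.w)
                        if self.col_use[j])) - self._masked_ll(x)
            W = Lr - Lf
        else:
            y = revcomp_codes(x)
            U = int(sum(self.rtheta[j, y[j]] for j in range(self.w)
                        if self.col_use[j])) - self._masked_ll(y)
            W = Lf - Lr
        return float(self._final(U, W))

    # -- vectorized region scoring ---------------------------------------

    def _per_position_tables(self, arr: np.ndarray):
        m = self.m
        La = len(arr)
        valid = arr < N_CODE
        codes_m = rolling_codes(arr, m) if m > 0 else np.zeros(La + 1, np.int64)
        cv = np.zeros(La, dtype=np.int64)  # conditional at position k (k>=m)
        cvalid = np.ones(La, dtype=bool)
        if La > m:
            cm1 = rolling_codes(arr, m + 1)
            ok = cm1 >= 0
            cv[m:][ok] = self.rcond[cm1[ok] >> 2, cm1[ok] & 3]
            cvalid[m:] = ok
        cvalid[:m] = valid[:m]
        return valid, codes_m, cv, cvalid

    def score_array(self, arr: np.ndarray):
        """Scores of every w-window of a code array, both strands.

        Returns (plus, minus) float arrays of length len(arr)-w+1 with NaN
        at windows containing N.
        """
        w, m = self.w, self.m
        La = len(arr)
        n = La - w + 1
        if n <= 0:
            return np.empty(0), np.empty(0)
        rc_all = revcomp_codes(arr)

        valid, codes_m, cv, _ = self._per_position_tables(arr)
        _, codes_m_rc, cv_rc, _ = self._per_position_tables(rc_all)

        # PWM sums, forward and reverse-complement match
        Tn = np.column_stack([self.rtheta, np.zeros(w, np.int64)])
        Tr = np.column_stack([self.rtheta_rc, np.zeros(w, np.int64)])
        A_plus = np.zeros(n, dtype=np.int64)
        A_minus = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for j in range(w):
            col = arr[j : j + n].astype(np.int64)
            if self.col_use[j]:
                A_plus += Tn[j, col]
            if self.col_use_rc[j]:
                A_minus += Tr[j, col]
            bad |= ~valid[j : j + n]

        # forward window log-likelihood (full and mask-respecting)
        C = np.concatenate([[0], np.cumsum(cv)])
        pi_f = (self.rpi[codes_m[:n]] if m > 0 else np.zeros(n, np.int64))
        Lf = pi_f + (C[np.arange(n) + w] - C[np.arange(n) + m])
        if self.col_use.all():
            Lf_masked = Lf
        else:
            # mask-respecting forward sum: drop conditionals at masked cols
            Lf_masked = pi_f.copy()
            for k in range(m, w):
                if self.col_use[k]:
                    Lf_masked = Lf_masked + cv[k : k + n]
        # reverse-complement window log-likelihood via the rc array
        Crc = np.concatenate([[0], np.cumsum(cv_rc)])
        if m > 0:
            pi_r = self.rpi[codes_m_rc[La - w - np.arange(n)]]
        else:
            pi_r = np.zeros(n, np.int64)
        Lr = pi_r + (Crc[La - np.arange(n)] - Crc[La - np.arange(n) - w + m])
        if self.col_use_rc.all():
            Lr_masked = Lr
        else:
            Lr_masked = pi_r.copy()
            for k in range(m, w):
                if self.col_use_rc[k]:
                    # conditional of rc window position k sits at rc_all
                    # index (La - i - w) + k for window start i
                    Lr_masked = Lr_masked + cv_rc[La - w + k - np.arange(n)]

        U_plus = A_plus - Lf_masked
        U_minus = A_minus - Lr_masked
        W = Lr - Lf
        plus = self._final(U_plus, W)
        minus = self._final(U_minus, -W)
        plus[bad] = np.nan
        minus[bad] = np.nan
        return plus, minus


def default_column_mask(pwm: PWM, background: MarkovBackground | None = None,
                        min_bits: float = 0.1) -> np.ndarray:
    """Weak-column mask: False (ignored) for columns with information
    content below ``min_bits``."""
    from .motif import information_content

    percol, _ = information_content(pwm, background)
    return percol >= min_bits


def site_score(pwm: PWM, background: MarkovBackground, seq_window,
               strand: str = "+", null_mode: str = "avg_strands",
               column_mask=None) -> float | None:
    """Discretized log2 likelihood-ratio score of a single window (None if
    the window contains N)."""
    return SiteScorer(pwm, background, null_mode, column_mask).score_window(
        seq_window, strand)


# ---------------------------------------------------------------------------
# exact null distribution / threshold learning
# ---------------------------------------------------------------------------


def _lr_piece_tables(scorer: SiteScorer):
    """For the DP: tables over (ctx, b) of the delayed reverse-strand
    conditional piece, the next context, and per-ctx finalization terms."""
    m = scorer.m
    if m == 0:
        nxt = np.zeros((1, 4), np.int64)
        lr = np.array([[int(scorer.rcond[0, 3 - b]) for b in range(4)]])
        fin = np.zeros(1, np.int64)
        return lr, nxt, fin
    nctx = 4**m
    mask = nctx - 1
    lr = np.zeros((nctx, 4), np.int64)
    nxt = np.zeros((nctx, 4), np.int64)
    fin = np.zeros(nctx, np.int64)
    for c in range(nctx):
        digits = [(c >> (2 * (m - 1 - i))) & 3 for i in range(m)]  # c_0..c_{m-1}
        # reverse-complement m-mer code for the final stationary term
        rc = 0
        for d in digits[::-1]:
            rc = (rc << 2) | (3 - d)
        fin[c] = scorer.rpi[rc]
        for b in range(4):
            nxt[c, b] = ((c << 2) | b) & mask
            # y-context order: comp(b), comp(c_{m-1}), ..., comp(c_1)
            yctx = 3 - b
            for d in digits[:0:-1]:
                yctx = (yctx << 2) | (3 - d)
            lr[c, b] = scorer.rcond[yctx, 3 - digits[0]]
    return lr, nxt, fin


def _null_distribution_dp(scorer: SiteScorer, state_budget: int):
    """Exact distribution of the discretized score under the background.

    Returns (scores ascending, probabilities). Raises _BudgetExceeded when
    the sparse state space grows past ``state_budget``.
    """
    w, m = scorer.w, scorer.m
    lr_tab, nxt_tab, fin_tab = _lr_piece_tables(scorer)
    cond = scorer.background.cond
    states: dict[tuple[int, int, int], float] = {}
    if m == 0:
        states[(0, 0, 0)] = 1.0
    else:
        pi = scorer.background.pi
        for c in range(4**m):
            U0 = -int(scorer.rpi[c])
            digits = [(c >> (2 * (m - 1 - i))) & 3 for i in range(m)]
            for j, d in enumerate(digits):
                if scorer.col_use[j]:
                    U0 += int(scorer.rtheta[j, d])
            W0 = -int(scorer.rpi[c])
            key = (c, U0, W0)
            states[key] = states.get(key, 0.0) + float(pi[c])
    for k in range(m, w):
        new: dict[tuple[int, int, int], float] = {}
        use = scorer.col_use[k]
        for (c, U, W), p in states.items():
            for b in range(4):
                pb = p * cond[c, b]
                dU = (int(scorer.rtheta[k, b]) - int(scorer.rcond[c, b])) if use else 0
                dW = int(lr_tab[c, b]) - int(scorer.rcond[c, b])
                key = (int(nxt_tab[c, b]), U + dU, W + dW)
                new[key] = new.get(key, 0.0) + pb
        states = new
        if len(states) > state_budget:
            raise _BudgetExceeded(len(states))
    dist: dict[float, float] = {}
    for (c, U, W), p in states.items():
        s = float(scorer._final(U, W + int(fin_tab[c])))
        dist[s] = dist.get(s, 0.0) + p
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    return scores, probs


def learn_threshold(pwm: PWM, background: MarkovBackground, pvalue: float = 1e-4,
                    method: str = "auto", null_mode: str = "avg_strands",
                    column_mask=None, state_budget: int = 2_000_000,
                    mc_draws: int = 200_000, seed: int = 0) -> ScoreThreshold:
    """Learn the score cutoff t* with null tail probability <= pvalue.

    ``method`` is "exact-DP", "monte-carlo" or "auto" (exact DP with a
    Monte-Carlo fallback once the sparse DP state space exceeds the
    budget).
    """
    if not (0 < pvalue <= 1):
        raise ValueError("pvalue must be in (0, 1]")
    scorer = SiteScorer(pwm, background, null_mode, column_mask)
    used = method
    # The DP's sparse state count grows with the number of reachable
    # (context, U, W) triples, which explodes with motif width; for wide
    # motifs go straight to Monte Carlo instead of growing to the budget.
    if method == "auto" and (scorer.w > 12 or (4**scorer.m) * scorer.w > 2048):
        used = method = "monte-carlo"
    if method in ("auto", "exact-DP"):
        try:
            scores, probs = _null_distribution_dp(scorer, state_budget)
            used = "exact-DP"
        except _BudgetExceeded:
            if method == "exact-DP":
                raise MemoryError("DP state budget exceeded; use monte-carlo")
            used = "monte-carlo"
    if used in ("monte-carlo",) or method == "monte-carlo":
        used = "monte-carlo"
        rng = np.random.default_rng(seed)
        wins = background.sample_windows(scorer.w, mc_draws, rng)
        vals = _score_windows_2d(scorer, wins)
        uniq, cnt = np.unique(vals, return_counts=True)
        scores, probs = uniq, cnt / cnt.sum()
    tail = probs[::-1].cumsum()[::-1]
    ok = tail <= pvalue + 1e-12
    cutoff = float(scores[ok][0]) if ok.any() else float(scores[-1] + GRID)
    if pvalue >= 1.0:
        cutoff = float(scores[0])
    return ScoreThreshold(pvalue=pvalue, cutoff=cutoff, method=used,
                          scores=scores, tail=tail)


def _score_windows_2d(scorer: SiteScorer, wins: np.ndarray) -> np.ndarray:
    """Vectorized plus-strand scores of an (n, w) array of windows."""
    n, w = wins.shape
    m = scorer.m
    U = np.zeros(n, dtype=np.int64)
    Lf = np.zeros(n, dtype=np.int64)
    Lr = np.zeros(n, dtype=np.int64)
    rc = 3 - wins[:, ::-1]
    if m > 0:
        cf = np.zeros(n, dtype=np.int64)
        cr = np.zeros(n, dtype=np.int64)
        for j in range(m):
            cf = (cf << 2) | wins[:, j]
            cr = (cr << 2) | rc[:, j]
        Lf += scorer.rpi[cf]
        Lr += scorer.rpi[cr]
        mask = (1 << (2 * m)) - 1
    else:
        cf = cr = np.zeros(n, dtype=np.int64)
        mask = 0
    for j in range(w):
        if scorer.col_use[j]:
            U += scorer.rtheta[j, wins[:, j]]
    Lf_masked = Lf.copy()
    for k in range(m, w):
        step_f = scorer.rcond[cf, wins[:, k]]
        step_r = scorer.rcond[cr, rc[:, k]]
        Lf += step_f
        Lr += step_r
        if scorer.col_use[k]:
            Lf_masked += step_f
        cf = ((cf << 2) | wins[:, k]) & mask
        cr = ((cr << 2) | rc[:, k]) & mask
    return scorer._final(U - Lf_masked, Lr - Lf)


# ---------------------------------------------------------------------------
# region scanning
# ---------------------------------------------------------------------------


def _cutoff_of(threshold) -> float:
    if threshold is None:
        return -np.inf
    if isinstance(threshold, ScoreThreshold):
        return threshold.cutoff
    return float(threshold)


def _region_seq(genome, region) -> np.ndarray:
    return encode(genome[region.chrom].seq[region.start : region.end])


def scan_regions(pwm: PWM, background: MarkovBackground, regions, genome,
                 threshold=None, mask: RegionMask | None = None,
                 column_mask=None, null_mode: str = "avg_strands",
                 scorer: SiteScorer | None = None) -> list[ScanHit]:
    """Score every window of every region on both strands; report hits at
    or above the threshold, excluding those overlapping the mask. Windows
    containing N are skipped; regions shorter than the motif yield no hits.
    """
    if scorer is None:
        scorer = SiteScorer(pwm, background, null_mode, column_mask)
    cutoff = _cutoff_of(threshold)
    w = scorer.w
    hits: list[ScanHit] = []
    for region in regions:
        arr = _region_seq(genome, region)
        if len(arr) < w:
            continue
        plus, minus = scorer.score_array(arr)
        for strand, scores in (("+", plus), ("-", minus)):
            idx = np.flatnonzero(np.nan_to_num(scores, nan=-np.inf)
                                 >= cutoff - 1e-9)
            for i in idx:
                s0 = region.start + int(i)
                if mask is not None and mask.overlaps(region.chrom, s0, s0 + w):
                    continue
                hits.append(ScanHit(region.chrom, s0, s0 + w, strand,
                                    float(scores[i]), region_id=region.region_id))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def best_match(pwm: PWM, background: MarkovBackground, region, genome,
               null_mode: str = "avg_strands",
               scorer: SiteScorer | None = None) -> ScanHit | None:
    """The maximal-score window of a region across both strands, with a
    deterministic tie-break (lowest start, then + strand). None when the
    region is shorter than the motif or all windows contain N."""
    if scorer is None:
        scorer = SiteScorer(pwm, background, null_mode)
    arr = _region_seq(genome, region)
    if len(arr) < scorer.w:
        return None
    plus, minus = scorer.score_array(arr)
    both = np.stack([plus, minus])
    if np.all(np.isnan(both)):
        return None
    flat = np.nan_to_num(both, nan=-np.inf)
    best_val = flat.max()
    # tie-break: lowest start, then '+' strand
    cand = []
    for si in (0, 1):
        idx = np.flatnonzero(flat[si] == best_val)
        if idx.size:
            cand.append((int(idx[0]), si))
    i, si = min(cand)
    s0 = region.start + i
    return ScanHit(region.chrom, s0, s0 + scorer.w, "+" if si == 0 else "-",
                   float(best_val), region_id=region.region_id)


def gapped_scan(pwm: PWM, background: MarkovBackground, regions, genome,
                gap_position: int, gap_lengths=(1, 2, 3), threshold=None,
                mask: RegionMask | None = None,
                null_mode: str = "avg_strands") -> list[ScanHit]:
    """Scan allowing a deletion of g genomic bases at a fixed PWM position.

    A window of length w+g is scored by deleting g bases at ``gap_position``
    before PWM scoring; the null is the background likelihood of the full
    w+g window (both-strand averaged). g=0 reproduces ungapped scores.
    """
    scorer = SiteScorer(pwm, background, null_mode)
    w, m = scorer.w, scorer.m
    if not (0 < gap_position < w):
        raise ValueError("gap_position must be inside the motif")
    cutoff = _cutoff_of(threshold)
    hits: list[ScanHit] = []
    for region in regions:
        arr = _region_seq(genome, region)
        for g in gap_lengths:
            wg = w + g
            n = len(arr) - wg + 1
            if n <= 0:
                continue
            for i in range(n):
                win = arr[i : i + wg]
                if np.any(win == N_CODE):
                    continue
                Lf = scorer._full_ll(win)
                Lr = scorer._full_ll(revcomp_codes(win))
                for strand in ("+", "-"):
                    x = win if strand == "+" else revcomp_codes(win)
                    xd = np.concatenate([x[:gap_position], x[gap_position + g:]])
                    U = int(sum(scorer.rtheta[j, xd[j]] for j in range(w)))
                    # null on the full window; pwm part on the deleted seq
                    if strand == "+":
                        U -= Lf
                        W = Lr - Lf
                    else:
                        U -= Lr
                        W = Lf - Lr
                    sc = float(scorer._final(U, W))
                    if sc >= cutoff - 1e-9:
                        s0 = region.start + i
                        if mask is not None and mask.overlaps(
                                region.chrom, s0, s0 + wg):
                            continue
                        hits.append(ScanHit(
                            region.chrom, s0, s0 + wg, strand, sc,
                            gap=(gap_position, g) if g > 0 else None,
                            region_id=region.region_id))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.end))
    return hits


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------


def window_overlap_frac(a_start, a_end, b_start, b_end) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return ov / min(a_end - a_start, b_end - b_start)


def same_locus(a: ScanHit | CandidateRecord, b, frac: float = 0.5) -> bool:
    """Two windows are the same locus when they overlap by >= frac of the
    shorter one (and share a chromosome)."""
    ach = a.chrom
    a0, a1 = (a.start, a.end) if isinstance(a, ScanHit) else (a.acs_start, a.acs_end)
    bch = b.chrom
    b0, b1 = (b.start, b.end) if isinstance(b, ScanHit) else (b.acs_start, b.acs_end)
    return ach == bch and window_overlap_frac(a0, a1, b0, b1) >= frac


def _find_region(regions_by_chrom, chrom, center):
    lst = regions_by_chrom.get(chrom)
    if not lst:
        return None
    starts = [r.start for r in lst]
    i = bisect.bisect_right(starts, center) - 1
    if i >= 0 and lst[i].start <= center < lst[i].end:
        return lst[i]
    return None


def rank_candidates(hits, intergenes, prior_verified=(), prior_tested=(),
                    batch_target: int = 20, intergenic_only: bool = True,
                    desert_bonus: float | None = None,
                    flank: int = 200) -> list[CandidateRecord]:
    """Compile the next verification batch from scan hits.

    Hits overlapping previously verified or previously tested loci are
    removed; intergene membership is decided by the center position of the
    hit; one candidate (its best hit) is kept per intergene; candidates are
    sorted by score descending and the batch cut is placed at the smallest
    size >= batch_target that does not split a tie in grid score. With
    ``desert_bonus`` = lambda, the ranking key becomes score + lambda *
    (distance to the nearest verified locus, normalized by the largest such
    distance among candidates). With ``intergenic_only=False``, hits outside
    intergenes are admitted and flagged ``in_coding``.
    """
    regions_by_chrom: dict[str, list] = {}
    for r in sorted(intergenes, key=lambda r: (r.chrom, r.start)):
        regions_by_chrom.setdefault(r.chrom, []).append(r)
    prior = list(prior_verified) + list(prior_tested)

    def overlaps_prior(h: ScanHit) -> bool:
        for p in prior:
            p0, p1 = (p.start, p.end) if hasattr(p, "start") else (p.acs_start, p.acs_end)
            pch = p.chrom
            if pch == h.chrom and p0 < h.end and p1 > h.start:
                return True
        return False

    best_per_region: dict[str, ScanHit] = {}
    coding: list[ScanHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.chrom, h.start, h.strand)):
        if overlaps_prior(h):
            continue
        region = _find_region(regions_by_chrom, h.chrom, h.center)
        if region is None:
            if intergenic_only:
                continue
            if not any(same_locus(h, c) for c in coding):
                coding.append(h)
            continue
        if region.region_id not in best_per_region:
            best_per_region[region.region_id] = h

    cands = [(h, False) for h in best_per_region.values()] + [
        (h, True) for h in coding]

    if desert_bonus is not None and prior_verified:
        centers: dict[str, list[int]] = {}
        for p in prior_verified:
            p0, p1 = (p.start, p.end) if hasattr(p, "start") else (p.acs_start, p.acs_end)
            centers.setdefault(p.chrom, []).append((p0 + p1) // 2)
        dists = []
        for h, _ in cands:
            cs = centers.get(h.chrom)
            dists.append(min(abs(h.center - c) for c in cs) if cs else 0)
        dmax = max(dists) or 1
        keyed = sorted(
            zip(cands, dists),
            key=lambda t: (-(t[0][0].score + desert_bonus * t[1] / dmax),
                           t[0][0].chrom, t[0][0].start))
        cands = [c for c, _ in keyed]
    else:
        cands.sort(key=lambda t: (-t[0].score, t[0].chrom, t[0].start))

    n = min(batch_target, len(cands))
    while n < len(cands) and cands[n][0].score == cands[n - 1][0].score:
        n += 1
    return [
        CandidateRecord(chrom=h.chrom, acs_start=h.start, acs_end=h.end,
                        strand=h.strand, score=h.score, status="pending",
                        flank=flank, in_coding=is_coding)
        for h, is_coding in cands[:n]
    ]
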