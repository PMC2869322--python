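"""ACS motif models: position weight matrices, Markov backgrounds, and
de-novo double-stranded Gibbs motif discovery.

The motif model is a fixed-width (50 bp by default) column-stochastic PWM
describing the ARS consensus sequence; the null model is an order-m Markov
chain trained on intergenic sequence. De-novo discovery is a ZOOPS
(zero-or-one-occurrence-per-sequence) Gibbs sampler scoring both strands,
selecting across random restarts the solution of maximal total information
content relative to the background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import ALPHABET, N_CODE, encode, revcomp_codes, rolling_codes

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MarkovBackground",
    "MotifSearchConfig",
    "GibbsResult",
    "fit_markov",
    "pwm_from_sites",
    "gibbs_motif_search",
    "information_content",
]


class PWM:
    """Column-stochastic probability matrix of a fixed-width motif.

    Parameters
    ----------
    probs
        Array of shape (w, 4), rows are motif positions, columns the bases
        in A, C, G, T order. Every row must sum to 1 and be strictly
        positive (apply a pseudocount when building from counts).
    pseudocount
        The pseudocount used when the matrix was derived from site counts;
        recorded for provenance.
    n_sites
        Number of training sites behind the matrix, if known.
    provenance
        Free-form description (site list, iteration id, exclusions).
    """

    def __init__(
        self,
        probs: np.ndarray,
        pseudocount: float = 0.01,
        n_sites: int | None = None,
        provenance: str = "",
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PWM must have shape (w, 4), got {probs.shape}")
        if np.any(probs < 0):
            raise ValueError("PWM probabilities must be nonnegative")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("PWM columns must each sum to 1 (within 1e-9)")
        self.probs = probs
        self.pseudocount = pseudocount
        self.n_sites = n_sites
        self.provenance = provenance

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log2_probs(self) -> np.ndarray:
        return np.log2(self.probs)

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.probs[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            n_sites=self.n_sites,
            provenance=self.provenance + " (revcomp)",
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, PWM) and np.array_equal(self.probs, other.probs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PWM(w={self.width}, n_sites={self.n_sites})"


def pwm_from_sites(sites, pseudocount: float = 0.01, provenance: str = "") -> PWM:
    """Build a PWM from aligned, equal-length DNA site strings.

    theta[j, b] = (count[j, b] + c) / (n + 4 c). Permutation-invariant in
    the site list. Raises on length mismatch or non-ACGT characters.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    counts = np.zeros((w, 4), dtype=float)
    for s in sites:
        if len(s) != w:
            raise ValueError(f"site length {len(s)} != {w}: {s!r}")
        codes = encode(s)
        if np.any(codes == N_CODE):
            raise ValueError(f"non-ACGT character in site {s!r}")
        counts[np.arange(w), codes] += 1.0
    n = len(sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    return PWM(probs, pseudocount=pseudocount, n_sites=n, provenance=provenance)


# ---------------------------------------------------------------------------
# Markov background
# ---------------------------------------------------------------------------


def _stationary_mmer(cond: np.ndarray, order: int) -> np.ndarray:
    """Stationary distribution over m-mer contexts of the chain."""
    nctx = cond.shape[0]
    if order == 0:
        return np.ones(1)
    mask = nctx - 1
    pi = np.full(nctx, 1.0 / nctx)
    for _ in range(100_000):
        nxt = np.zeros(nctx)
        for b in range(4):
            dest = ((np.arange(nctx) << 2) | b) & mask
            np.add.at(nxt, dest, pi * cond[:, b])
        if np.abs(nxt - pi).sum() < 1e-13:
            pi = nxt
            break
        pi = nxt
    return pi / pi.sum()


class MarkovBackground:
    """Order-m Markov model of background (intergenic) sequence.

    ``cond[c, b]`` is P(next base = b | preceding m-mer with code c); all
    conditionals are strictly positive and each context row sums to 1.
    ``pi`` is the stationary distribution over m-mer contexts, used to start
    window likelihoods and to sample sequence.
    """

    def __init__(self, cond: np.ndarray, order: int, trained_on: str = ""):
        cond = np.asarray(cond, dtype=float)
        if cond.shape != (4**order, 4):
            raise ValueError(f"cond must have shape ({4 ** order}, 4)")
        if np.any(cond < 0):
            raise ValueError("conditionals must be nonnegative")
        if np.any(np.abs(cond.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each context's conditionals must sum to 1")
        self.cond = cond
        self.order = order
        self.trained_on = trained_on
        self.pi = _stationary_mmer(cond, order)
        # stationary single-base distribution (marginal of the last context base)
        if order == 0:
            self.stationary_base = cond[0].copy()
        else:
            last = np.arange(4**order) & 3
            self.stationary_base = np.bincount(last, weights=self.pi, minlength=4)

    def log2_cond(self) -> np.ndarray:
        return np.log2(self.cond)

    def log2_pi(self) -> np.ndarray:
        return np.log2(self.pi)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample n bases from the stationary chain; returns codes."""
        m = self.order
        if m == 0:
            return rng.choice(4, size=n, p=self.cond[0]).astype(np.int8)
        ctx = int(rng.choice(len(self.pi), p=self.pi))
        u = rng.random(n)
        cum = np.cumsum(self.cond, axis=1)
        return _sample_chain(cum, m, ctx, u)

    def sample_windows(self, w: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample n independent length-w windows from the stationary chain.

        Vectorized across windows; used by Monte-Carlo threshold learning.
        """
        m = self.order
        out = np.empty((n, w), dtype=np.int8)
        if m == 0:
            out[:] = rng.choice(4, size=(n, w), p=self.cond[0])
            return out
        ctx = rng.choice(len(self.pi), size=n, p=self.pi)
        c = ctx.copy()
        for i in range(m - 1, -1, -1):
            out[:, i] = c & 3
            c >>= 2
        mask = (1 << (2 * m)) - 1
        cum = np.cumsum(self.cond, axis=1)
        for j in range(m, w):
            u = rng.random(n)
            b = (u[:, None] >= cum[ctx]).sum(axis=1)
            out[:, j] = b
            ctx = ((ctx << 2) | b) & mask
        return out


def _sample_chain_py(cum, order, ctx, u):
    n = len(u)
    out = np.empty(n, dtype=np.int8)
    mask = (1 << (2 * order)) - 1
    for i in range(n):
        r = u[i]
        row = cum[ctx]
        b = 0
        while b < 3 and r >= row[b]:
            b += 1
        out[i] = b
        ctx = ((ctx << 2) | b) & mask
    return out


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _sample_chain = njit(cache=False)(_sample_chain_py)
except Exception:  # pragma: no cover
    _sample_chain = _sample_chain_py


def fit_markov(seqs, order: int = 4, pseudocount: float = 0.5,
               trained_on: str = "") -> MarkovBackground:
    """Fit an order-m background from sequences (strings or code arrays).

    Conditionals are (count + pc) / (context_total + 4 pc); windows
    containing N are skipped. Warns when the corpus is shorter than
    4^(order+1) bases.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty training set")
    total = 0
    counts = np.zeros(4 ** (order + 1), dtype=float)
    for s in seqs:
        arr = encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.int8)
        total += len(arr)
        codes = rolling_codes(arr, order + 1)
        codes = codes[codes >= 0]
        if len(codes):
            counts += np.bincount(codes, minlength=4 ** (order + 1))
    if total < 4 ** (order + 1):
        warnings.warn(
            f"training length {total} < 4^{order + 1}; conditionals will be "
            "dominated by the pseudocount", stacklevel=2)
    counts = counts.reshape(4**order, 4)
    ctx_tot = counts.sum(axis=1, keepdims=True)
    if pseudocount == 0:
        # contexts never observed fall back to uniform
        cond = np.where(ctx_tot > 0, counts / np.where(ctx_tot == 0, 1, ctx_tot), 0.25)
    else:
        cond = (counts + pseudocount) / (ctx_tot + 4 * pseudocount)
    return MarkovBackground(cond, order, trained_on=trained_on)


# ---------------------------------------------------------------------------
# Gibbs motif discovery
# ---------------------------------------------------------------------------


@dataclass
class MotifSearchConfig:
    """Configuration of the ZOOPS Gibbs motif search.

    ``site_prior`` is the prior probability mass of the "no site" option in
    each sequence's placement posterior (the remaining mass is spread
    uniformly over all valid placements on both strands). ``selection`` is
    always best total information content across restarts.
    """

    width: int = 50
    site_prior: float = 0.05
    markov_order: int = 4
    double_stranded: bool = True
    n_restarts: int = 200
    max_sweeps: int = 200
    pseudocount: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.site_prior < 1):
            raise ValueError("site_prior must be in (0, 1)")
        if self.width < 2:
            raise ValueError("width must be >= 2")


@dataclass
class GibbsResult:
    pwm: PWM
    sites: list  # per-sequence (pos, strand) or None
    information: float
    per_column_bits: np.ndarray = field(repr=False, default=None)


def information_content(pwm: PWM, background: MarkovBackground | None = None):
    """Per-column relative entropy (bits) of the PWM against the
    background's stationary base distribution (uniform if no background),
    and its total.
    """
    q = background.stationary_base if background is not None else np.full(4, 0.25)
    theta = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(theta > 0, theta * (np.log2(np.where(theta > 0, theta, 1))
                                             - np.log2(q)), 0.0)
    percol = terms.sum(axis=1)
    return percol, float(percol.sum())


def _normalize_orientation(probs: np.ndarray) -> tuple[np.ndarray, bool]:
    """Canonical strand: the A+T-richer half-site leads; ties broken by the
    lexicographically smaller consensus."""
    rc = probs[::-1, ::-1]
    h = probs.shape[0] // 2 or 1
    at_f = probs[:h, [0, 3]].sum()
    at_r = rc[:h, [0, 3]].sum()
    if abs(at_f - at_r) > 1e-12:
        return (probs, False) if at_f >= at_r else (rc.copy(), True)
    cons_f = "".join(ALPHABET[i] for i in probs.argmax(axis=1))
    cons_r = "".join(ALPHABET[i] for i in rc.argmax(axis=1))
    return (probs, False) if cons_f <= cons_r else (rc.copy(), True)


def _window_bg_log2(arr: np.ndarray, background: MarkovBackground, w: int) -> np.ndarray:
    """log2 background likelihood of each w-window of arr (conditional on
    the actual preceding context; stationary base marginals for the first m
    positions of the sequence). -inf where the window contains N."""
    m = background.order
    L = len(arr)
    lc = np.full(L, -np.inf)
    valid = arr < N_CODE
    lsb = np.log2(background.stationary_base)
    head = min(m, L)
    idx = arr[:head].astype(int)
    lc[:head] = np.where(valid[:head], lsb[np.clip(idx, 0, 3)], -np.inf)
    if L > m:
        codes = rolling_codes(arr, m + 1)
        l2c = background.log2_cond()
        ok = codes >= 0
        vals = np.full(len(codes), -np.inf)
        cc = codes[ok]
        vals[ok] = l2c[cc >> 2, cc & 3]
        lc[m:] = vals
    n = L - w + 1
    if n <= 0:
        return np.empty(0)
    with np.errstate(invalid="ignore"):
        cs = np.concatenate([[0.0], np.cumsum(lc)])
        out = cs[w:] - cs[:-w]
    # windows containing N must be -inf, not NaN
    bad = np.zeros(n, dtype=bool)
    for j in range(w):
        bad |= ~valid[j : j + n]
    out[bad] = -np.inf
    return out


def _pwm_scores_all(arr: np.ndarray, log2theta: np.ndarray) -> np.ndarray:
    """Sum_j log2 theta[j, arr[i+j]] for every start i (N -> -inf)."""
    w = log2theta.shape[0]
    n = len(arr) - w + 1
    if n <= 0:
        return np.empty(0)
    T = np.column_stack([log2theta, np.full(w, -np.inf)])  # N column
    out = np.zeros(n)
    for j in range(w):
        out += T[j, arr[j : j + n]]
    return out


def gibbs_motif_search(seqs, background: MarkovBackground,
                       config: MotifSearchConfig) -> GibbsResult:
    """ZOOPS Gibbs sampler for a fixed-width motif on both strands.

    Per sweep each sequence's site (or its absence) is resampled from the
    posterior under the PWM built from all other sequences' current sites;
    across restarts the assignment maximizing total information content of
    the resulting PWM is returned. Fully reproducible given the seed.
    """
    w = config.width
    arrs = [encode(s) if isinstance(s, str) else np.asarray(s, np.int8) for s in seqs]
    for a in arrs:
        if len(a) < w:
            raise ValueError(f"sequence shorter than motif width {w}")
    n_seq = len(arrs)
    bg_ll = [_window_bg_log2(a, background, w) for a in arrs]
    rcs = [revcomp_codes(a) for a in arrs]
    c = config.pseudocount
    p0 = config.site_prior

    best = None
    for restart in range(config.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, restart)))
        # current assignment: (pos, strand) with strand in {+1,-1}, or None
        sites: list = []
        counts = np.zeros((w, 4))
        n_sites = 0
        for i, a in enumerate(arrs):
            valid = np.flatnonzero(np.isfinite(bg_ll[i]))
            if len(valid) == 0 or rng.random() < p0:
                sites.append(None)
                continue
            pos = int(rng.choice(valid))
            strand = 1 if (not config.double_stranded or rng.random() < 0.5) else -1
            sites.append((pos, strand))
            win = a[pos : pos + w] if strand == 1 else revcomp_codes(a[pos : pos + w])
            counts[np.arange(w), win] += 1
            n_sites += 1

        for _sweep in range(config.max_sweeps):
            changed = False
            for i, a in enumerate(arrs):
                cur = sites[i]
                if cur is not None:
                    pos, strand = cur
                    win = a[pos : pos + w] if strand == 1 else revcomp_codes(a[pos : pos + w])
                    counts[np.arange(w), win] -= 1
                    n_sites -= 1
                theta = (counts + c) / (max(n_sites, 0) + 4 * c)
                lt = np.log2(theta)
                lw_plus = _pwm_scores_all(a, lt) - bg_ll[i]
                cands = [lw_plus]
                if config.double_stranded:
                    # motif on - strand: score rc(seq) windows, map back
                    lw_minus = (_pwm_scores_all(rcs[i], lt) - bg_ll[i][::-1])[::-1]
                    cands.append(lw_minus)
                lw = np.concatenate(cands)
                finite = np.isfinite(lw)
                npl = int(finite.sum())
                if npl == 0:
                    sites[i] = None
                    continue
                mx = lw[finite].max()
                wts = np.where(finite, np.exp2(np.clip(lw - mx, -700, 50)), 0.0)
                none_wt = p0 / (1 - p0) * npl * np.exp2(-mx) if mx < 600 else 0.0
                tot = wts.sum() + none_wt
                r = rng.random() * tot
                if r >= wts.sum():
                    new = None
                else:
                    k = int(np.searchsorted(np.cumsum(wts), r, side="right"))
                    L = len(lw_plus)
                    new = (k, 1) if k < L else (k - L, -1)
                if new != cur:
                    changed = True
                sites[i] = new
                if new is not None:
                    pos, strand = new
                    win = a[pos : pos + w] if strand == 1 else revcomp_codes(a[pos : pos + w])
                    counts[np.arange(w), win] += 1
                    n_sites += 1
            if not changed:
                break

        if n_sites == 0:
            continue
        theta = (counts + c) / (n_sites + 4 * c)
        pwm = PWM(theta, pseudocount=c, n_sites=n_sites,
                  provenance=f"gibbs restart {restart}")
        _, ic = information_content(pwm, background)
        if best is None or ic > best[0] + 1e-12:
            best = (ic, theta, list(sites), n_sites)

    if best is None:
        raise RuntimeError("no restart produced a non-empty site assignment")
    ic, theta, sites, n_sites = best
    norm, flipped = _normalize_orientation(theta)
    if flipped:
        sites = [None if s is None else (s[0], -s[1]) for s in sites]
    pwm = PWM(norm, pseudocount=c, n_sites=n_sites, provenance="gibbs best-IC")
    percol, total = information_content(pwm, background)
    return GibbsResult(pwm=pwm, sites=sites, information=total, per_column_bits=percol)
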