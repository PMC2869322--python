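"""Comparative-genomics statistics for origin maps.

Synteny is defined on adjacent gene pairs: a pair of adjacent genes in
species A is syntenically conserved with a pair of adjacent genes in
species B when the genes are pairwise homologous (BLAST-style E-value below
a cutoff, consumed from a precomputed table) and their relative
orientations are conserved - identical strand patterns, or the whole pair
inverted. An intergene is syntenic iff its flanking adjacent gene pair is.

Association tests use the exact two-sided hypergeometric p-value with the
doubling convention (twice the smaller tail, capped at 1), and a
length-adjusted Monte-Carlo null that places each ARS independently into an
intergene with probability proportional to intergene length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "HomologyTable",
    "SyntenyAssignment",
    "AssociationResult",
    "OrientationCounts",
    "find_syntenic_pairs",
    "hypergeom_two_sided",
    "length_adjusted_test",
    "trna_association",
    "flanking_orientation",
]


class HomologyTable:
    """Cross-species gene homology pairs with alignment E-values."""

    def __init__(self, pairs: pd.DataFrame, cutoff: float = 1e-4):
        cols = list(pairs.columns[:3])
        df = pairs.rename(columns=dict(zip(cols, ["gene_a", "gene_b", "evalue"])))
        if (df["evalue"] < 0).any():
            raise ValueError("negative E-value")
        self.cutoff = cutoff
        df = df[df["evalue"] < cutoff]
        self._a2b: dict[str, set] = {}
        self._b2a: dict[str, set] = {}
        for ga, gb in zip(df["gene_a"], df["gene_b"]):
            self._a2b.setdefault(str(ga), set()).add(str(gb))
            self._b2a.setdefault(str(gb), set()).add(str(ga))

    @classmethod
    def from_tsv(cls, path, cutoff: float = 1e-4) -> "HomologyTable":
        return cls(pd.read_csv(path, sep="\t"), cutoff=cutoff)

    def homologous(self, gene_a: str, gene_b: str) -> bool:
        return gene_b in self._a2b.get(gene_a, ())

    def partners_of_a(self, gene_a: str):
        return self._a2b.get(gene_a, set())


@dataclass
class SyntenyAssignment:
    """Per-species view of the syntenic adjacent-pair analysis."""

    n_pairs_total: int  # adjacent pairs (internal intergenes)
    syntenic_pairs: set  # frozenset-free: tuples of (left, right) names
    n_syntenic: int
    intergene_syntenic: dict  # (chrom, left, right) -> bool


@dataclass
class AssociationResult:
    n_population: int
    k_marked: int
    n_sample: int
    k_observed: int
    p_two_sided: float
    p_length_adjusted: float | None = None
    n_draws: int | None = None
    seed: int | None = None
    null_model: str = "random intergene"


@dataclass
class OrientationCounts:
    fr: int  # convergent: both flanking genes transcribe toward the ARS
    rf: int  # divergent: both transcribe away
    ffrr: int  # tandem: one toward, one away (ff + rr pooled)
    n_skipped_terminal: int = 0

    @property
    def n_ars(self) -> int:
        return self.fr + self.rf + self.ffrr


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------


def _adjacent_pairs(genes):
    """Consecutive gene pairs per chromosome; genes must be coordinate
    sorted within each chromosome."""
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = []
    for chrom, gs in by_chrom.items():
        starts = [g.start for g in gs]
        if starts != sorted(starts):
            raise ValueError(f"gene list not coordinate-ordered on {chrom}")
        pairs.extend(zip(gs, gs[1:]))
    return pairs


def _orientation_conserved(a1, a2, b1, b2) -> bool:
    """Same ordered strand pattern, or the whole pair inverted (the same
    locus read from the other strand)."""
    flip = {"+": "-", "-": "+"}
    return ((a1.strand, a2.strand) == (b1.strand, b2.strand)
            or (a1.strand, a2.strand) == (flip[b2.strand], flip[b1.strand]))


def find_syntenic_pairs(genes_a, genes_b, homology: HomologyTable):
    """Syntenically conserved adjacent gene pairs between two species.

    Returns (pair_of_pairs list, assignment_a, assignment_b). A pair of
    adjacent genes in A matches a pair of adjacent genes in B either in
    direct order (a1~b1, a2~b2) or crossed (a1~b2, a2~b1, seen when the
    pair is inverted in B), provided orientations are conserved.
    """
    pairs_a = _adjacent_pairs(genes_a)
    pairs_b = _adjacent_pairs(genes_b)
    # index B pairs by member gene names for fast candidate lookup
    by_member: dict[str, list] = {}
    for pb in pairs_b:
        by_member.setdefault(pb[0].name, []).append(pb)
        by_member.setdefault(pb[1].name, []).append(pb)

    matches = []
    syn_a, syn_b = set(), set()
    for a1, a2 in pairs_a:
        cands = {id(pb): pb for h in (homology.partners_of_a(a1.name)
                                      | homology.partners_of_a(a2.name))
                 for pb in by_member.get(h, [])}
        for pb in cands.values():
            b1, b2 = pb
            direct = (homology.homologous(a1.name, b1.name)
                      and homology.homologous(a2.name, b2.name)
                      and _orientation_conserved(a1, a2, b1, b2))
            crossed = (homology.homologous(a1.name, b2.name)
                       and homology.homologous(a2.name, b1.name)
                       and _orientation_conserved(a1, a2,
                                                  _flipped(b2), _flipped(b1)))
            if direct or crossed:
                matches.append(((a1, a2), (b1, b2)))
                syn_a.add((a1.name, a2.name))
                syn_b.add((b1.name, b2.name))

    def assignment(pairs, syn, chrom_of):
        return SyntenyAssignment(
            n_pairs_total=len(pairs),
            syntenic_pairs=set(syn),
            n_syntenic=len(syn),
            intergene_syntenic={
                (p[0].chrom, p[0].name, p[1].name): (p[0].name, p[1].name) in syn
                for p in pairs})

    return (matches,
            assignment(pairs_a, syn_a, 0),
            assignment(pairs_b, syn_b, 1))


def _flipped(g):
    from dataclasses import replace as dc_replace

    return dc_replace(g, strand="+" if g.strand == "-" else "-")


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------


def hypergeom_two_sided(N: int, K: int, n: int, k: int) -> float:
    """Exact two-sided hypergeometric p-value, doubling convention.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for X ~ Hypergeom(N, K, n),
    with both tails obtained by exact summation of the PMF.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    kmin, kmax = max(0, n - (N - K)), min(K, n)
    if not (kmin <= k <= kmax):
        raise ValueError(f"k={k} outside support [{kmin},{kmax}]")
    lower = float(np.sum(hypergeom.pmf(np.arange(kmin, k + 1), N, K, n)))
    upper = float(np.sum(hypergeom.pmf(np.arange(k, kmax + 1), N, K, n)))
    return min(1.0, 2.0 * min(lower, upper))


def length_adjusted_test(lengths, marked, n_ars: int, k_observed: int,
                         n_draws: int = 100_000, seed: int = 0) -> float:
    """Two-sided Monte-Carlo p-value under a length-adjusted null.

    Each of ``n_ars`` ARSs is placed independently into an intergene with
    probability proportional to its length; a draw's statistic is the
    number of ARSs landing in marked intergenes (equivalently a binomial
    draw with success probability = marked length fraction). The two-sided
    p doubles the smaller empirical tail, capped at 1, with the +1
    correction that keeps p >= 1/(n_draws+1).
    """
    lengths = np.asarray(lengths, dtype=float)
    marked = np.asarray(marked, dtype=bool)
    if np.any(lengths <= 0):
        raise ValueError("all intergene lengths must be positive")
    if n_draws < 1000:
        warnings.warn("n_draws < 1000 gives a coarse Monte-Carlo p-value",
                      stacklevel=2)
    p_marked = lengths[marked].sum() / lengths.sum()
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_ars, p_marked, size=n_draws)
    c_low = int((draws <= k_observed).sum())
    c_high = int((draws >= k_observed).sum())
    p = 2.0 * (1 + min(c_low, c_high)) / (n_draws + 1)
    return min(1.0, p)


def trna_association(intergenes, ars_counts, adjust_length: bool = False,
                     n_draws: int = 100_000, seed: int = 0) -> AssociationResult:
    """Association between ARSs and tRNA-containing intergenes.

    ``ars_counts`` maps region_id -> number of ARSs in that intergene (or
    is an iterable of region_ids, one per ARS). Runs the exact
    hypergeometric test and, optionally, the length-adjusted Monte-Carlo
    null.
    """
    if not isinstance(ars_counts, dict):
        counts: dict[str, int] = {}
        for rid in ars_counts:
            counts[rid] = counts.get(rid, 0) + 1
        ars_counts = counts
    N = len(intergenes)
    K = sum(1 for r in intergenes if r.contains_trna)
    n = sum(ars_counts.values())
    k = sum(ars_counts.get(r.region_id, 0) for r in intergenes if r.contains_trna)
    if n == 0 or N == 0:
        p = 1.0
    else:
        # ARS-level counts can exceed the without-replacement support when
        # an intergene holds several ARSs; truncate to the support boundary
        # (the length-adjusted MC null has no such restriction)
        n_h = min(n, N)
        k_h = min(max(k, max(0, n_h - (N - K))), min(K, n_h))
        p = hypergeom_two_sided(N, K, n_h, k_h)
    res = AssociationResult(n_population=N, k_marked=K, n_sample=n,
                            k_observed=k, p_two_sided=p)
    if adjust_length and n > 0:
        res.p_length_adjusted = length_adjusted_test(
            [r.length for r in intergenes],
            [r.contains_trna for r in intergenes], n, k,
            n_draws=n_draws, seed=seed)
        res.n_draws = n_draws
        res.seed = seed
        res.null_model = "random intergene + length-adjusted MC"
    return res


# ---------------------------------------------------------------------------
# flanking-gene orientation
# ---------------------------------------------------------------------------


def flanking_orientation(ars_centers, intergenes) -> OrientationCounts:
    """Classify ARSs by the transcription direction of their flanking
    genes: fr = convergent (left +, right -), rf = divergent (left -,
    right +), ff+rr = tandem. ARSs in terminal intergenes (a missing
    flanking gene) are skipped and counted separately."""
    by_chrom: dict[str, list] = {}
    for r in intergenes:
        by_chrom.setdefault(r.chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: r.start)
    fr = rf = ffrr = skipped = 0
    for chrom, center in ars_centers:
        region = None
        for r in by_chrom.get(chrom, []):
            if r.start <= center < r.end:
                region = r
                break
        if region is None or region.left_gene is None or region.right_gene is None:
            skipped += 1
            continue
        ls, rs = region.left_gene.strand, region.right_gene.strand
        if (ls, rs) == ("+", "-"):
            fr += 1
        elif (ls, rs) == ("-", "+"):
            rf += 1
        else:
            ffrr += 1
    return OrientationCounts(fr=fr, rf=rf, ffrr=ffrr,
                             n_skipped_terminal=skipped)
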