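"""Synthetic annotated genomes with planted ACS instances, and the
synthetic verification oracle.

The generator emulates the statistical structure the origin-mapping method
assumes: an order-m Markov background at yeast-like A+T content, genes
alternating with intergenes whose lengths follow two lognormal classes (a
shorter "syntenic-like" and a longer "nonsyntenic-like" class, echoing the
observed 398 bp vs 655 bp asymmetry), occasional tRNAs inside intergenes,
and N sites sampled from a ground-truth 50 bp PWM with an inverted-repeat
dimeric structure, planted almost exclusively in intergenes. Sites are
sampled from the PWM rather than a fixed consensus so that detection rates
below 1 arise naturally; a temperature parameter sharpens (<1) or flattens
(>1) the truth PWM to control motif strength.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from ._seq import decode, encode, revcomp_codes
from .genome_io import Feature, IntergenicRegion, SequenceRecord, Site
from .iterate import OracleResult
from .motif import PWM, MarkovBackground

__all__ = [
    "SimConfig",
    "Truth",
    "SimResult",
    "SyntenyScenario",
    "generate_genome",
    "synthetic_oracle",
    "make_synteny_scenario",
]


@dataclass
class SimConfig:
    """Study conditions of the synthetic genome.

    Lengths in bp; rates in [0, 1]. ``temperature`` controls motif
    strength: 1.0 is the moderate default, ~0.4 gives a strong,
    near-consensus motif.
    """

    n_chromosomes: int = 2
    chrom_length: int = 250_000
    gene_log_mean: float = 7.15  # lognormal; mean length ~1.4 kb
    gene_log_sigma: float = 0.45
    intergene_mean_syntenic: float = 398.0
    intergene_mean_nonsyntenic: float = 655.0
    intergene_log_sigma: float = 0.6
    frac_syntenic_class: float = 0.5
    background_order: int = 4
    background_at: float = 0.62
    background_concentration: float = 12.0
    motif_width: int = 50
    dimeric: bool = True
    temperature: float = 1.0
    n_sites: int = 150
    intergenic_fraction: float = 0.98
    plant_weighting: str = "uniform"  # or "length"
    ars_class_bias: float = 1.0  # nonsyntenic-class planting weight
    trna_fraction: float = 0.08
    trna_length: int = 75
    false_negative: float = 0.0
    false_positive: float = 0.0
    unclonable: float = 0.04
    seed: int = 0

    def __post_init__(self):
        for r in (self.false_negative, self.false_positive, self.unclonable,
                  self.intergenic_fraction, self.frac_syntenic_class):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.plant_weighting not in ("uniform", "length"):
            raise ValueError("plant_weighting must be 'uniform' or 'length'")


@dataclass
class Truth:
    sites: list  # planted Site records (strand = orientation planted)
    pwm: PWM
    intergenes: list  # IntergenicRegion, as laid out by the generator
    class_labels: dict  # region_id -> "syntenic-like" | "nonsyntenic-like"
    trnas: list  # tRNA Features
    background: MarkovBackground
    config: SimConfig


@dataclass
class SimResult:
    genome: dict  # chrom -> SequenceRecord
    features: list  # gene + tRNA Features
    truth: Truth

    def intergenic_sequences(self) -> list:
        return [self.genome[r.chrom].seq[r.start : r.end]
                for r in self.truth.intergenes]


# half-site consensus and per-position strength classes of the truth motif;
# an AT-rich patchy pattern; the full motif is half + spacer + inverted
# repeat of the half. Strength classes: s(trong), m(oderate), w(eak).
_HALF = [("T", "s"), ("T", "s"), ("T", "m"), ("T", "s"), ("A", "m"),
         ("T", "s"), ("G", "w"), ("T", "m"), ("T", "s"), ("T", "s"),
         ("A", "w"), ("G", "m"), ("T", "s"), ("T", "m"), ("T", "s"),
         ("G", "w"), ("A", "m"), ("T", "s"), ("T", "s"), ("T", "m"),
         ("A", "w"), ("T", "m")]
_Q = {"s": 0.85, "m": 0.60, "w": 0.45}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def truth_pwm(config: SimConfig) -> PWM:
    """Deterministic ground-truth PWM from the fixed dimeric profile."""
    w = config.motif_width
    cols = []
    for base, cls in _HALF:
        q = _Q[cls]
        col = np.full(4, (1 - q) / 3)
        col[_BASE_IDX[base]] = q
        cols.append(col)
    half = np.array(cols)
    spacer_len = w - 2 * len(half) if config.dimeric else w - len(half)
    spacer = np.tile(np.array([0.30, 0.20, 0.20, 0.30]), (max(spacer_len, 0), 1))
    if config.dimeric:
        probs = np.vstack([half, spacer, half[::-1, ::-1]])
    else:
        probs = np.vstack([half, spacer])
    probs = probs[:w]
    # temperature: sharpen (<1) or flatten (>1)
    probs = probs ** (1.0 / config.temperature)
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(probs, pseudocount=1e-9, n_sites=None,
               provenance=f"synthetic truth (temperature={config.temperature})")


def _random_background(config: SimConfig, rng: np.random.Generator) -> MarkovBackground:
    at = config.background_at
    base = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    m = config.background_order
    cond = rng.dirichlet(config.background_concentration * base * 4, size=4**m)
    cond = np.clip(cond, 1e-6, None)
    cond /= cond.sum(axis=1, keepdims=True)
    return MarkovBackground(cond, m, trained_on="synthetic generator")


def _lognormal_len(rng, mean, sigma, lo):
    mu = np.log(mean) - sigma**2 / 2
    return max(int(round(rng.lognormal(mu, sigma))), lo)


def generate_genome(config: SimConfig) -> SimResult:
    """Sample a genome, its annotation, and the planted ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    background = _random_background(config, rng)
    pwm = truth_pwm(config)
    w = config.motif_width

    genome: dict[str, SequenceRecord] = {}
    features: list[Feature] = []
    intergenes: list[IntergenicRegion] = []
    class_labels: dict[str, str] = {}
    genes_by_chrom: dict[str, list[Feature]] = {}

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        seq = background.sample(L, rng)
        pos = 0
        gene_idx = 0
        chrom_genes: list[Feature] = []
        chrom_inter: list[tuple[int, int, str]] = []
        while pos < L:
            if rng.random() < config.frac_syntenic_class:
                cls, mean = "syntenic-like", config.intergene_mean_syntenic
            else:
                cls, mean = "nonsyntenic-like", config.intergene_mean_nonsyntenic
            gi = _lognormal_len(rng, mean, config.intergene_log_sigma, 20)
            end_i = min(pos + gi, L)
            if end_i > pos:
                chrom_inter.append((pos, end_i, cls))
            pos = end_i
            if pos >= L:
                break
            gl = _lognormal_len(rng, np.exp(config.gene_log_mean
                                            + config.gene_log_sigma**2 / 2),
                                config.gene_log_sigma, 300)
            end_g = min(pos + gl, L)
            if end_g - pos >= 100:
                gene_idx += 1
                chrom_genes.append(Feature(
                    chrom, pos, end_g, "+" if rng.random() < 0.5 else "-",
                    "gene", f"{chrom}_g{gene_idx:04d}"))
            else:
                # tail too short for a gene: extend the last intergene
                s0, _, cls0 = chrom_inter[-1]
                chrom_inter[-1] = (s0, end_g, cls0)
            pos = end_g
        genome[chrom] = SequenceRecord(chrom, decode(seq))
        genes_by_chrom[chrom] = chrom_genes
        features.extend(chrom_genes)
        for s, e, cls in chrom_inter:
            region = IntergenicRegion(chrom, s, e, terminal=(s == 0 or e == L))
            intergenes.append(region)
            class_labels[region.region_id] = cls

    # tRNAs inside intergenes
    trnas: list[Feature] = []
    for r in intergenes:
        if r.length >= config.trna_length + 20 and rng.random() < config.trna_fraction:
            off = int(rng.integers(10, r.length - config.trna_length - 9))
            t = Feature(r.chrom, r.start + off, r.start + off + config.trna_length,
                        "+" if rng.random() < 0.5 else "-", "tRNA",
                        f"t{r.chrom}_{r.start + off}")
            trnas.append(t)
            r.contains_trna = True
    features.extend(trnas)

    # plant sites
    n_inter = int(round(config.n_sites * config.intergenic_fraction))
    n_coding = config.n_sites - n_inter
    eligible = [r for r in intergenes if r.length >= w + 4]
    if n_inter > len(eligible):
        raise ValueError(
            f"cannot plant {n_inter} intergenic sites in {len(eligible)} "
            "eligible intergenes; lower density or enlarge the genome")
    if config.plant_weighting == "length":
        wts = np.array([r.length - w + 1 for r in eligible], dtype=float)
    else:
        wts = np.ones(len(eligible))
    bias = np.array([config.ars_class_bias
                     if class_labels[r.region_id] == "nonsyntenic-like" else 1.0
                     for r in eligible])
    wts = wts * bias
    chosen = rng.choice(len(eligible), size=n_inter, replace=False,
                        p=wts / wts.sum())

    sites: list[Site] = []
    seq_arrays = {c: encode(genome[c].seq) for c in genome}

    def plant(chrom, start):
        inst = np.empty(w, dtype=np.int8)
        for j in range(w):
            inst[j] = rng.choice(4, p=pwm.probs[j])
        strand = "+" if rng.random() < 0.5 else "-"
        planted = inst if strand == "+" else revcomp_codes(inst)
        seq_arrays[chrom][start : start + w] = planted
        sites.append(Site(chrom, start, start + w,
                          name=f"site{len(sites) + 1:04d}", strand=strand))

    for idx in sorted(int(i) for i in chosen):
        r = eligible[idx]
        off = int(rng.integers(0, r.length - w + 1))
        plant(r.chrom, r.start + off)
    if n_coding > 0:
        all_genes = [g for gs in genes_by_chrom.values() for g in gs
                     if g.end - g.start >= w + 4]
        gidx = rng.choice(len(all_genes), size=n_coding, replace=False)
        for gi in sorted(int(i) for i in gidx):
            g = all_genes[gi]
            off = int(rng.integers(0, g.end - g.start - w + 1))
            plant(g.chrom, g.start + off)

    for c in genome:
        genome[c] = SequenceRecord(c, decode(seq_arrays[c]))

    truth = Truth(sites=sites, pwm=pwm, intergenes=intergenes,
                  class_labels=class_labels, trnas=trnas,
                  background=background, config=config)
    return SimResult(genome=genome, features=features, truth=truth)


# ---------------------------------------------------------------------------
# verification oracle
# ---------------------------------------------------------------------------


def _locus_rng(seed: int, chrom: str, start: int, end: int) -> np.random.Generator:
    key = zlib.crc32(f"{chrom}:{start}-{end}".encode())
    return np.random.default_rng(np.random.SeedSequence((seed, key)))


def synthetic_oracle(truth: Truth, false_negative: float | None = None,
                     false_positive: float | None = None,
                     unclonable: float | None = None, seed: int = 0,
                     overlap_frac: float = 0.5):
    """Oracle callable backed by the planted truth.

    A candidate is functional iff its ACS window overlaps a planted site by
    >= ``overlap_frac`` (of the shorter window), flipped with the
    configured false rates; unavailable with the unclonable rate. Noise is
    deterministic per locus, so re-querying a locus gives the same answer.
    Rates default to the generator config's.
    """
    cfg = truth.config
    fn = cfg.false_negative if false_negative is None else false_negative
    fp = cfg.false_positive if false_positive is None else false_positive
    uc = cfg.unclonable if unclonable is None else unclonable
    by_chrom: dict[str, list[Site]] = {}
    for s in truth.sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    def oracle(chrom, start, end, strand="+", seq=None) -> OracleResult:
        rng = _locus_rng(seed, chrom, start, end)
        if uc and rng.random() < uc:
            return OracleResult("unavailable", "unclonable")
        hit = False
        for s in by_chrom.get(chrom, []):
            ov = min(end, s.end) - max(start, s.start)
            if ov > 0 and ov / min(end - start, s.end - s.start) >= overlap_frac:
                hit = True
                break
        if hit and fn and rng.random() < fn:
            hit = False
        elif not hit and fp and rng.random() < fp:
            hit = True
        return OracleResult("functional" if hit else "nonfunctional")

    return oracle


# ---------------------------------------------------------------------------
# paired-genome synteny scenario
# ---------------------------------------------------------------------------


@dataclass
class SyntenyScenario:
    genes_a: list  # Features, ordered along chromosomes
    genes_b: list
    homology: "object"  # pandas DataFrame: gene_a, gene_b, evalue
    intergenes_a: list  # internal intergenes of genome A
    broken_adjacencies: set  # frozenset({left_name, right_name}) broken in B
    ars_sites: list  # Sites planted in A intergene centers
    config: "SyntenySimConfig"


@dataclass
class SyntenySimConfig:
    n_genes: int = 200
    n_chromosomes: int = 2
    n_rearrangements: int = 20
    gene_length: int = 1000
    intergene_length: int = 400
    n_ars: int = 40
    nonsyntenic_bias: float = 1.0  # planting weight for broken-adjacency intergenes
    seed: int = 0


def make_synteny_scenario(config: SyntenySimConfig) -> SyntenyScenario:
    """Genome B = genome A after sampled gene-order rearrangements
    (segment inversions and translocations within a chromosome); the
    homology table lists the true orthologs with strong E-values."""
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    per_chrom = config.n_genes // config.n_chromosomes
    orders_a, orders_b = [], []
    for ci in range(config.n_chromosomes):
        names = [f"g{ci + 1}_{i + 1:04d}" for i in range(per_chrom)]
        strands = ["+" if rng.random() < 0.5 else "-" for _ in names]
        orders_a.append(list(zip(names, strands)))
        orders_b.append(list(zip(names, strands)))

    broken: set[frozenset] = set()

    def adjacencies(order):
        return [frozenset((order[i][0], order[i + 1][0]))
                for i in range(len(order) - 1)]

    for _ in range(config.n_rearrangements):
        ci = int(rng.integers(config.n_chromosomes))
        order = orders_b[ci]
        if len(order) < 4:
            continue
        i = int(rng.integers(0, len(order) - 2))
        j = int(rng.integers(i + 1, min(i + 9, len(order))))
        seg = order[i:j + 1]
        before = set(adjacencies(order))
        if rng.random() < 0.5:
            # inversion: reverse order, flip strands
            order[i:j + 1] = [(n, "+" if s == "-" else "-")
                              for n, s in seg[::-1]]
        else:
            del order[i:j + 1]
            k = int(rng.integers(0, len(order) + 1))
            order[k:k] = seg
        after = set(adjacencies(order))
        for a in before - after:
            broken.add(a)
        broken -= after  # restored adjacencies are not broken

    def layout(orders, species):
        feats = []
        gl, il = config.gene_length, config.intergene_length
        for ci, order in enumerate(orders):
            pos = il
            for name, strand in order:
                feats.append(Feature(f"{species}chr{ci + 1}", pos, pos + gl,
                                     strand, "gene", name))
                pos += gl + il
        return feats

    genes_a = layout(orders_a, "A")
    genes_b = layout(orders_b, "B")
    homology = pd.DataFrame({
        "gene_a": [n for order in orders_a for n, _ in order],
        "gene_b": [n for order in orders_a for n, _ in order],
        "evalue": 1e-50,
    })

    # internal intergenes of A, flanked by consecutive genes
    intergenes_a: list[IntergenicRegion] = []
    by_chrom: dict[str, list[Feature]] = {}
    for g in genes_a:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.start)
        for left, right in zip(gs, gs[1:]):
            intergenes_a.append(IntergenicRegion(
                chrom, left.end, right.start, left_gene=left, right_gene=right))

    # plant ARSs with optional preference for broken-adjacency intergenes
    wts = np.array([
        config.nonsyntenic_bias
        if frozenset((r.left_gene.name, r.right_gene.name)) in broken else 1.0
        for r in intergenes_a])
    n_ars = min(config.n_ars, len(intergenes_a))
    chosen = rng.choice(len(intergenes_a), size=n_ars, replace=False,
                        p=wts / wts.sum())
    ars_sites = []
    for i in sorted(int(x) for x in chosen):
        r = intergenes_a[i]
        c = (r.start + r.end) // 2
        ars_sites.append(Site(r.chrom, c - 25, c + 25,
                              name=f"ars{i:04d}", strand="+"))

    return SyntenyScenario(genes_a=genes_a, genes_b=genes_b, homology=homology,
                           intergenes_a=intergenes_a, broken_adjacencies=broken,
                           ars_sites=ars_sites, config=config)
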