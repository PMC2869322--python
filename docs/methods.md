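# Methods

## The problem

A naive genome — one with no replication-origin map — can be mapped by
alternating computational prediction with functional verification.
Autonomously replicating sequences (ARSs) act as a plasmid-based proxy for
replication origins; in budding yeasts they are governed by a defined ARS
consensus sequence (ACS) that a position weight matrix (PWM) can model. The
package implements the full loop: learn a 50 bp ACS PWM from verified
sites, scan the genome for high-scoring matches relative to an intergenic
Markov background, propose a ranked candidate batch, verify it through an
oracle (an assay-result table, or a synthetic truth), fold new positives
back into the model, and finally project the total repertoire size with a
confidence interval, plus the comparative statistics (synteny, tRNA
co-localization, flanking-gene orientation) used to interpret the map.

## Scoring model

A window `x` of width `w` is scored

    score(x) = log2 [ P_pwm(x) / Pbar_bg(x) ]

where `Pbar_bg` is the arithmetic mean of the background likelihoods of
the window and of its reverse complement. This averaged-strands null makes
a site's score invariant to which strand carries the match; a per-strand
null is available behind `null_mode="per_strand"`. Window likelihoods
start from the stationary m-mer distribution of the order-m background
chain (windows are scored as self-contained objects, without flanking
context, so region-local and genome-wide scans agree).

**Discretization.** Scores are kept on a 0.01 grid: every elementary log2
quantity (a PWM column term, a background conditional, a stationary m-mer
term) is rounded to the grid before summation. The per-site error is
bounded by half a grid step per term. The payoff is an *exact* null
distribution: because contributions are integers on the grid, a dynamic
program over Markov contexts can enumerate the joint distribution of

- `U` — the PWM-versus-forward-likelihood grid score, and
- `W` — the reverse-versus-forward grid log-ratio,

with reverse-strand contributions emitted with an m-step delay (the
conditional of a base on the reverse strand depends on the m following
bases, which are known m emissions later). The final score is
`U·grid − log2((1 + 2^(W·grid))/2)`, rounded to the grid. The DP's states
are sparse dictionaries keyed by (context, U, W); its result equals
brute-force enumeration over all `4^w` windows *exactly*, which the test
suite verifies for `w ≤ 5` and orders 0–2. For production sizes (w=50,
order 4) the state space is far past any reasonable budget, and threshold
learning switches to seeded Monte Carlo (default 10^5–2·10^5 windows
sampled from the stationary chain); at the operating p-value of 1e-4 this
locates the cutoff to within a few grid steps.

The threshold `t*` is the smallest grid score whose null tail probability
is at most the requested p-value (default 1e-4), so
`P_null(score ≥ t*) ≤ p*` and the next lower grid score violates the
bound.

**Gapped (dimeric) scanning.** The ACS has an inverted-repeat dimeric
character, and a spacer of variable length between the half-sites is
biologically plausible. A gapped scan scores a window of length `w+g` by
deleting `g` genomic bases at a fixed motif position before PWM scoring;
the null is the background likelihood of the *full* `w+g` window (both
strands averaged), so gapped and ungapped scores are on the same footing
and `g=0` reproduces the ungapped scan identically.

**Column masking.** An optional boolean mask drops weak PWM columns (by
default those under 0.1 bits) from both the PWM term and the corresponding
forward-likelihood term. Masked columns inside the first m positions keep
the null's initial stationary term intact (the m-mer term is joint and
cannot be decomposed per column); the option is intended for exploratory
rescanning, not for threshold-calibrated prediction.

## Motif learning

`pwm_from_sites` builds the PWM from aligned fixed-width windows with a
pseudocount (default 0.01): `θ[j,b] = (count + c)/(n + 4c)`.

De-novo discovery (`gibbs_motif_search`) is a ZOOPS Gibbs sampler: each
sequence carries either one site (on either strand when double-stranded)
or none. Per sweep, a sequence's placement is resampled from its posterior
under the PWM built from all other sequences' current sites; the prior
probability mass of the "no site" option is `site_prior` (default 0.05),
the rest spread uniformly over placements. Across restarts (default 200
restarts × 200 sweeps; tests use far fewer) the assignment maximizing the
total information content of the resulting PWM is kept. Information
content is per-column relative entropy against the background's stationary
base distribution. The final PWM orientation is normalized so the
A+T-richer half leads, with a lexicographic consensus tie-break; windows
containing N are excluded from placement. The sampler is bit-for-bit
reproducible given the seed, verified by test.

On tiny instances the sampler's selection score is checked against
exhaustive enumeration of all placements; note the ZOOPS "none" option
means the sampler may legitimately exceed the all-sites enumeration
optimum, so the check is a one-sided bound.

## Predict-and-verify loop

Each cycle: (1) re-learn the PWM from all verified sites, after excluding
near-duplicate training windows (≥ 90% identity keeps the first site by
coordinate — telomeric ARS families would otherwise bias the matrix);
(2) learn the score threshold at p = 1e-4; (3) scan the intergenes (the
vast majority of real sites are intergenic; coding-region candidates can
be admitted and are then flagged); (4) rank candidates — one per
intergene, previously proposed or verified loci excluded, batch cut at the
smallest size ≥ the target (default 20) that does not split a tie in grid
score, mirroring the practice of letting discrete scores slightly enlarge
a batch; (5) verify each candidate through the oracle; (6) append
outcomes to the ledger and fold functional sites into the training set.
Two windows are "the same locus" when they overlap by at least half the
shorter window. Unclonable candidates are never re-proposed and are
excluded from performance ratios. An optional `desert_bonus` adds
λ × (normalized distance to the nearest verified site) to the ranking
key, prioritizing long ARS-free stretches.

The loop rebuilds the PWM from fixed-width verified windows each cycle
rather than re-running de-novo discovery; de-novo search is the entry
point when the initial screen provides fragments without aligned windows.

## Repertoire-size estimation

The screen is assumed to be a uniform random sample of the unknown
repertoire **S**. Leave-one-out (LOO) detection: hold out each screened
site, train the PWM on the remaining n−1, take the best match inside the
held-out site's intergene, and call it detected at threshold t when it
localizes to the true window (≥ 50% overlap) and scores ≥ t. With d(t)
the LOO detection rate and V(t) the number of verified sites found
genome-wide at or above t, the point estimate is `N̂ = max(V, round(V/d))`
and the interval inverts exact binomial (Clopper–Pearson) bounds
(d_lo, d_hi) on d:

    L = max(V, ceil(V / d_hi)),    U = ceil(V / d_lo).

Both rounding choices are conservative against understating the
repertoire. V is treated as observed without error (the assay is the gold
standard); the LOO rate is slightly pessimistic (trained on n−1 sites),
which biases N̂ upward — again conservative in the direction that matters.
The construction is validated by simulation rather than by appeal to a
closed-form coverage theorem: `coverage_simulation` plants a known number
of sites, reveals a random screen, runs the full LOO + estimation path
(V is obtained the way a real study obtains it — scan every intergene
with the screen PWM and verify hits against the truth), and reports how
often the upper bound falls below the truth. The acceptance run (100
replicates, two 250 kb chromosomes, order-4 background, 150 planted
intergenic sites, 69-site screens) keeps that miss-low rate within 5%,
the property a 95% interval should have. Because d enters through its
lower bound, weak motifs widen the interval instead of breaking coverage.

## Comparative statistics

**Synteny.** Two adjacent gene pairs (one per species) are syntenically
conserved when the genes are pairwise homologous (E-value below 1e-4 in a
precomputed table) and the ordered strand pattern matches either directly
or after whole-pair inversion — adjacency read from the other strand is
the same locus. An intergene inherits the synteny of its flanking pair; a
pair may support multiple cross-species matches, so distinct-pair counts
are reported per species. Swapping the species leaves the syntenic pair
set invariant (tested).

**Two-sided hypergeometric tests** use the doubling convention:
`p = min(1, 2·min(P(X ≤ k), P(X ≥ k)))` by exact PMF summation. The
convention is pinned by a published contingency table whose doubled value
is 0.51 while the minimum-likelihood convention gives ≈ 0.25. When
ARS-level counts exceed the without-replacement support (several ARSs in
one marked intergene), the count is truncated to the support boundary;
the Monte-Carlo null below has no such restriction.

**Length adjustment.** Longer intergenes collect more sites under any
random-placement null, so raw hypergeometric association can be an
artifact of length (tRNA-containing intergenes, in particular, are much
longer than average). The adjusted null places each ARS independently in
an intergene with probability proportional to its length; the marked-hit
count per draw is then exactly a binomial draw with the marked length
fraction as success probability, which is how it is sampled. The
two-sided Monte-Carlo p doubles the smaller empirical tail with the
(1 + count)/(draws + 1) correction, capped at 1; with equal lengths it
converges to the exact doubled binomial p (tested against the closed
form).

**Flanking orientation.** ARSs are positioned by the center of their best
ACS match and classified by flanking gene strands: fr (convergent — both
genes transcribe toward the ARS), rf (divergent), ff+rr (tandem, pooled).
ARSs in terminal intergenes are skipped and counted separately.

## Synthetic genomes

The generator emulates the statistical structure the method assumes, not
yeast biology: an order-4 Markov background at 62% A+T (per-context
conditionals drawn once per genome from a Dirichlet centered on the base
composition); genes (lognormal lengths, mean ≈ 1.4 kb) alternating with
intergenes drawn from two lognormal classes — a shorter "syntenic-like"
(mean 398 bp) and a longer "nonsyntenic-like" (mean 655 bp) class, so
length-adjusted tests have a real confound to correct; tRNAs inside a
fraction (default 8%) of intergenes; and N sites (default 150) sampled
per-position from a ground-truth PWM, planted at most one per intergene,
98% intergenic by default.

The truth PWM is a fixed inverted-repeat dimer: two 22 bp AT-rich,
patchy half-sites around a 6 bp near-background spacer, with per-position
consensus probabilities 0.85/0.60/0.45 by strength class. Sites are
*sampled* from the PWM, not written as consensus, so detection rates below
1 arise naturally; a temperature parameter sharpens (< 1, "strong") or
flattens (> 1, "weak") the matrix. The default temperature 1.0 is the
moderate setting used for estimator validation; 0.4 is the strong setting
used for pipeline-recovery checks. The verification oracle flips truth
with configurable false-positive/negative rates and fails entirely
("unclonable") at a default rate of ~4%, the ledger shape a real screen
exhibits; noise is deterministic per locus so repeated queries agree.

What the generator does **not** emulate: chromatin and replication
timing, repeat families and telomeric structure, sequence evolution,
assay-specific biases (plasmid copy number, colony size), or correlated
verification errors. Passing tests therefore demonstrate the statistical
machinery, not performance on real genomes; the real published inputs
(genomes, assay ledgers, homology tables) flow through the same
interfaces when supplied.

The paired-genome synteny scenario derives genome B from A by segment
inversions and translocations, tracks exactly which adjacencies break,
and emits an ortholog table — giving the synteny analysis a fixture with
known truth (zero rearrangements → all syntenic; saturating
rearrangements → none).

## Numerical and design choices

- Score grid 0.01; per-element rounding (see above). Scores are stored as
  floats rounded to 2 decimals; the DP works in integer grid units.
- Stationary m-mer distribution by power iteration to 1e-13 total
  variation.
- Markov fit pseudocount 0.5 by default (Jeffreys-style); zero-count
  contexts fall back to uniform when fitted without pseudocount.
- Degenerate inputs: regions shorter than the motif yield no hits and no
  error; windows containing N are skipped everywhere; zero detection at a
  threshold raises rather than returning an unbounded interval; a
  zero-positive ledger reports an infinite negative:positive ratio flag.
- Ties: best match breaks ties by lowest start then + strand; batch cuts
  never split a grid-score tie; near-duplicate exclusion keeps the first
  site by coordinate.
- Problem sizes in the shipped validation runs were chosen to exercise
  the method end-to-end at desk scale: 100 coverage replicates on ~500 kb
  genomes, pipeline recovery on a ~1 Mb genome with 150 planted sites and
  a 69-site screen, and 20-seed direction checks on ~150 kb genomes.

## Known limitations

- The Monte-Carlo threshold at p = 1e-4 rests on the top ~10–20 of 10^5
  null draws; the cutoff is reproducible given the seed but carries a few
  grid steps of sampling noise. Exact DP is available whenever the state
  space is affordable.
- The estimator treats V as noiseless and d as binomial; correlation
  between the two (both depend on the same screen PWM) is not modeled,
  only shown by simulation to act conservatively under these conditions.
- The exact DP's memory is data-dependent; the budget guard falls back to
  Monte Carlo rather than attempting an out-of-core pass.
- Gapped scanning is per-window and markedly slower than the vectorized
  ungapped scan; it is intended for targeted follow-up, not routine
  genome-wide use.
- GenBank flatfiles are not parsed; inputs are FASTA plus GFF3/TSV.
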