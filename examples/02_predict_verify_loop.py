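"""Run the iterative predict-and-verify loop against a synthetic oracle.

Plants 150 sites in a ~1 Mb genome, reveals 69 as the initial screen, and
runs 5 cycles of PWM refinement -> scan -> ~20-candidate batch ->
verification, then reports the ledger and the recovery of the planted
repertoire.
"""

import numpy as np

from oriscout.iterate import IterateConfig, performance_ratio, run_predict_verify
from oriscout.motif import fit_markov
from oriscout.scanner import window_overlap_frac
from oriscout.synthetic import SimConfig, generate_genome, synthetic_oracle

cfg = SimConfig(n_chromosomes=2, chrom_length=500_000, n_sites=150,
                temperature=0.4, unclonable=0.0, seed=11)
sim = generate_genome(cfg)
background = fit_markov(sim.intergenic_sequences(), order=4)
oracle = synthetic_oracle(sim.truth)

intergenic = [s for s in sim.truth.sites
              if any(r.chrom == s.chrom and r.start <= s.start and s.end <= r.end
                     for r in sim.truth.intergenes)]
rng = np.random.default_rng(2)
screen = [intergenic[i]
          for i in sorted(rng.choice(len(intergenic), 69, replace=False))]
print(f"initial screen: {len(screen)} of {len(sim.truth.sites)} planted sites")

state = run_predict_verify(sim.genome, background, sim.truth.intergenes,
                           screen, oracle,
                           IterateConfig(batch_target=20, n_iterations=5, seed=5))
n_neg, n_pos, ratio = performance_ratio(state.ledger)
print(f"ledger: {len(state.ledger)} candidates over 5 cycles; "
      f"{n_pos} functional, {n_neg} nonfunctional (neg:pos = {ratio:.2f})")

functional = [c for c in state.ledger if c.status == "functional"]
covered = sum(
    any(s.chrom == x.chrom and window_overlap_frac(s.start, s.end, x.start, x.end) >= 0.5
        for x in screen)
    or any(s.chrom == c.chrom
           and window_overlap_frac(s.start, s.end, c.acs_start, c.acs_end) >= 0.5
           for c in functional)
    for s in sim.truth.sites)
print(f"repertoire recovery: {covered}/{len(sim.truth.sites)} planted sites "
      "verified functional (screen + predictions)")
print("interpretation: the loop converges on the planted repertoire; the "
      "negative:positive ratio rises in late batches as the supply of "
      "undiscovered sites runs out (diminishing returns).")
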