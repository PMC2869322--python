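"""The iterative predict-and-verify loop.

Each cycle re-learns the ACS PWM from all sites verified so far, scans the
intergenic regions for new high-scoring matches, compiles a batch of ~20
candidates that have not been proposed before, queries a verification
oracle (a table of assay outcomes, or the synthetic truth), and folds the
newly functional sites back into the training set. The ledger records every
candidate ever proposed, exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .genome_io import CandidateRecord, RegionMask, Site
from .motif import PWM, MarkovBackground, pwm_from_sites
from .scanner import learn_threshold, rank_candidates, scan_regions

__all__ = [
    "OracleResult",
    "IterateConfig",
    "IterationState",
    "table_oracle",
    "verify",
    "site_sequence",
    "training_sequences",
    "run_iteration",
    "run_predict_verify",
    "performance_ratio",
]


@dataclass
class OracleResult:
    status: str  # functional | nonfunctional | unavailable
    note: str = ""


@dataclass
class IterateConfig:
    batch_target: int = 20
    n_iterations: int = 5
    final_batch_target: int | None = None  # e.g. 41 for a last, larger cycle
    pvalue: float = 1e-4
    flank: int = 200
    pseudocount: float = 0.01
    identity_threshold: float = 0.9  # near-duplicate training-site exclusion
    overlap_frac: float = 0.5  # same-locus rule
    intergenic_only: bool = True
    desert_bonus: float | None = None
    mc_draws: int = 100_000
    seed: int = 0


@dataclass
class IterationState:
    iteration: int
    training_sites: list  # Site records whose windows train the PWM
    ledger: list  # CandidateRecord, every candidate ever proposed
    config: IterateConfig
    pwm: PWM | None = None
    screen_sites: list = field(default_factory=list)


def site_sequence(genome, site: Site, flank: int = 0) -> str:
    """Oriented sequence of a site's window (plus optional flanks)."""
    seq = genome[site.chrom].seq[max(site.start - flank, 0) : site.end + flank]
    return seq if site.strand != "-" else revcomp(seq)


def table_oracle(table):
    """Verification oracle backed by a table of assayed loci.

    ``table`` is a pandas DataFrame or CSV path with columns chrom, start,
    end, status. A query matching a recorded locus (>= 50% window overlap)
    returns its status; anything else is unavailable.
    """
    import pandas as pd

    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table
    rows = [(str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["status"]))
            for _, r in df.iterrows()]

    def oracle(chrom, start, end, strand="+", seq=None) -> OracleResult:
        for rch, rs, re_, status in rows:
            if rch != chrom:
                continue
            ov = min(end, re_) - max(start, rs)
            if ov > 0 and ov / min(end - start, re_ - rs) >= 0.5:
                return OracleResult(status, "table")
        return OracleResult("unavailable", "locus absent from table")

    return oracle


def verify(oracle, candidate: CandidateRecord, genome=None) -> OracleResult:
    """Query the oracle with the candidate's ACS window and flanking
    context; oracle failure maps to unavailable."""
    seq = None
    if genome is not None:
        s = max(candidate.acs_start - candidate.flank, 0)
        e = candidate.acs_end + candidate.flank
        seq = genome[candidate.chrom].seq[s:e]
    try:
        res = oracle(candidate.chrom, candidate.acs_start, candidate.acs_end,
                     candidate.strand, seq)
    except Exception as exc:  # noqa: BLE001 - oracle plumbing failure
        return OracleResult("unavailable", f"oracle failure: {exc}")
    if res.status not in ("functional", "nonfunctional", "unavailable"):
        return OracleResult("unavailable", f"bad oracle status {res.status!r}")
    return res


def training_sequences(genome, sites, identity_threshold: float = 0.9):
    """Oriented training windows with near-duplicate exclusion.

    Any site whose window is >= identity_threshold identical to an earlier
    (by coordinate) kept site contributes once. Returns (sequences,
    kept_sites).
    """
    from ._seq import encode

    ordered = sorted(sites, key=lambda s: (s.chrom, s.start, s.end))
    kept, seqs = [], []
    arrs_by_len: dict[int, list] = {}
    for s in ordered:
        seq = site_sequence(genome, s)
        arr = encode(seq)
        prev = arrs_by_len.get(len(seq))
        if prev:
            ident = (np.vstack(prev) == arr).mean(axis=1)
            if ident.max() >= identity_threshold:
                continue
        kept.append(s)
        seqs.append(seq)
        arrs_by_len.setdefault(len(seq), []).append(arr)
    return seqs, kept


def run_iteration(state: IterationState, genome, background: MarkovBackground,
                  oracle, intergenes, mask: RegionMask | None = None,
                  scan_regions_override=None) -> IterationState:
    """One predict-and-verify cycle; returns the updated state."""
    cfg = state.config
    if not state.training_sites:
        raise ValueError("empty training set")
    seqs, _kept = training_sequences(genome, state.training_sites,
                                     cfg.identity_threshold)
    pwm = pwm_from_sites(seqs, pseudocount=cfg.pseudocount,
                         provenance=f"iteration {state.iteration + 1}")
    threshold = learn_threshold(
        pwm, background, cfg.pvalue, method="auto",
        mc_draws=cfg.mc_draws,
        seed=int(np.random.SeedSequence(
            (cfg.seed, state.iteration)).generate_state(1)[0] % (2**31)))
    targets = scan_regions_override if scan_regions_override is not None else intergenes
    hits = scan_regions(pwm, background, targets, genome,
                        threshold=threshold, mask=mask)
    is_last = state.iteration + 1 == cfg.n_iterations
    target_n = (cfg.final_batch_target
                if (is_last and cfg.final_batch_target) else cfg.batch_target)
    batch = rank_candidates(
        hits, intergenes,
        prior_verified=state.training_sites,
        prior_tested=state.ledger,
        batch_target=target_n,
        intergenic_only=cfg.intergenic_only,
        desert_bonus=cfg.desert_bonus,
        flank=cfg.flank)
    new_training = list(state.training_sites)
    new_ledger = list(state.ledger)
    for cand in batch:
        cand.iteration = state.iteration + 1
        res = verify(oracle, cand, genome)
        cand.status = res.status
        new_ledger.append(cand)
        if res.status == "functional":
            new_training.append(Site(cand.chrom, cand.acs_start, cand.acs_end,
                                     name=f"iter{cand.iteration}",
                                     score=cand.score, strand=cand.strand))
    return IterationState(iteration=state.iteration + 1,
                          training_sites=new_training, ledger=new_ledger,
                          config=cfg, pwm=pwm, screen_sites=state.screen_sites)


def run_predict_verify(genome, background, intergenes, screen_sites, oracle,
                       config: IterateConfig,
                       mask: RegionMask | None = None) -> IterationState:
    """Run the full loop from an initial screen."""
    state = IterationState(iteration=0, training_sites=list(screen_sites),
                           ledger=[], config=config,
                           screen_sites=list(screen_sites))
    for _ in range(config.n_iterations):
        state = run_iteration(state, genome, background, oracle, intergenes,
                              mask=mask)
    return state


def performance_ratio(records):
    """Negative:positive ratio of resolved verification outcomes.

    Unavailable/pending records are excluded from both counts. Returns
    (n_negative, n_positive, ratio); ratio is inf when there are negatives
    but no positives, 0.0 when both are absent.
    """
    n_pos = sum(1 for r in records if r.status == "functional")
    n_neg = sum(1 for r in records if r.status == "nonfunctional")
    if n_pos == 0:
        ratio = math.inf if n_neg else 0.0
    else:
        ratio = n_neg / n_pos
    return n_neg, n_pos, ratio
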