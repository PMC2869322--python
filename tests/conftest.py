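import numpy as np
import pytest

from oriscout.genome_io import SequenceRecord
from oriscout.motif import MarkovBackground
from oriscout.synthetic import SimConfig, generate_genome


@pytest.fixture
def uniform_bg():
    return MarkovBackground(np.full((1, 4), 0.25), 0)


@pytest.fixture
def make_genome():
    """Build an in-memory genome dict from {chrom: sequence string}."""

    def _make(seqs: dict):
        return {c: SequenceRecord(c, s) for c, s in seqs.items()}

    return _make


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic genome shared by read-only tests: one 120 kb
    chromosome, 30 strongly planted intergenic sites."""
    cfg = SimConfig(n_chromosomes=1, chrom_length=120_000, n_sites=30,
                    intergenic_fraction=1.0, temperature=0.4,
                    unclonable=0.0, seed=42)
    return generate_genome(cfg)
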