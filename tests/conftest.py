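import numpy as np
import pytest

from equiphase.haplosim import LongReadParams, SimConfig, simulate_fragments, simulate_truth
from equiphase.iohap import Protocol


@pytest.fixture(scope="session")
def small_truth():
    """A 50 kb chromosome with 120 het SNVs and a fixed seed."""
    cfg = SimConfig(seed=11, chrom_length=50_000, n_het=120)
    return cfg, simulate_truth(cfg)


@pytest.fixture(scope="session")
def clean_longread_bundle():
    """Error-free long-read fragments densely covering a small chromosome."""
    cfg = SimConfig(
        seed=13,
        chrom_length=100_000,
        n_het=300,
        longread=LongReadParams(coverage=25, length_mean=8_000, allele_error=0.0),
    )
    truth = simulate_truth(cfg)
    frags = simulate_fragments(truth, cfg, Protocol.LONGREAD)
    return cfg, truth, frags


def hap_agrees_flipaware(pred_alleles, truth_alleles):
    """True iff two allele sequences agree up to one global flip."""
    same = all(a == b for a, b in zip(pred_alleles, truth_alleles))
    flipped = all(a == 1 - b for a, b in zip(pred_alleles, truth_alleles))
    return same or flipped
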