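import numpy as np
import pytest

from dnsatlas.genome import GenomeAssembly, GenomicInterval
from dnsatlas.core import compute_dns
from dnsatlas.synthetic import SyntheticConfig, generate_truth, simulate_reads


@pytest.fixture
def assembly():
    return GenomeAssembly([("1A", 100_000), ("1B", 100_000), ("1D", 80_000)])


@pytest.fixture
def iv():
    def make(chrom, start, end, strand="."):
        return GenomicInterval(chrom, start, end, strand)
    return make


@pytest.fixture(scope="session")
def small_truth():
    """Compact genome (6 x 1 Mb) for annotation-level tests."""
    cfg = SyntheticConfig(chrom_length=1_000_000, n_footprints=30)
    return generate_truth(cfg, seed=11)


@pytest.fixture(scope="session")
def mid_pipeline():
    """6 x 2 Mb genome run through the read->DNS pipeline once per session."""
    cfg = SyntheticConfig(chrom_length=2_000_000)
    truth = generate_truth(cfg, seed=5)
    samples = simulate_reads(truth, mean_depth=2.0, seed=105)
    per_rep, avg, raw = compute_dns(samples, truth.assembly)
    return {"truth": truth, "samples": samples, "per_rep": per_rep,
            "avg": avg, "raw": raw}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
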