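import numpy as np
import pytest

from stimgene.synthetic_data import BenchmarkConfig, make_benchmark

CODONS_SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


def random_cds(rng, n_codons=None) -> str:
    """A random valid CDS (start, sense codons, single terminal stop)."""
    n = int(rng.integers(5, 40)) if n_codons is None else n_codons
    body = "".join(rng.choice(CODONS_SENSE, size=n))
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + body + stop


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benchmark(tmp_path_factory):
    """A small synthetic benchmark shared by I/O-level tests."""
    out = tmp_path_factory.mktemp("bench")
    config = BenchmarkConfig(n_pos=60, n_neg=80, n_elg=5, graph_nodes=120, seed=7)
    make_benchmark(config, out)
    return out, config
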