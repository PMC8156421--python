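import numpy as np
import pytest

import drivercontext as dc


@pytest.fixture
def toy_genome(tmp_path):
    """Single-contig genome 'ACGTACGTACG' used for coordinate pinning."""
    path = tmp_path / "toy.fa"
    path.write_text(">ctg\nACGTACGTACG\n")
    return dc.open_genome(path)


@pytest.fixture(scope="session")
def separable_benchmark(tmp_path_factory):
    """Small fixture whose driver/passenger flank contexts are well separated."""
    outdir = tmp_path_factory.mktemp("bench_sep")
    spec = dc.SyntheticSpec(
        n_contigs=1, contig_length=40_000, n_drivers=100, n_passengers=300,
        driver_context=dc.markov_gc_rich(0.8),
        passenger_context=dc.markov_at_rich(0.8),
        seed=11,
    )
    genome_path, mutations, descriptive = dc.make_benchmark(spec, outdir)
    return dc.open_genome(genome_path), mutations, descriptive


@pytest.fixture(scope="session")
def exchangeable_benchmark(tmp_path_factory):
    """Fixture whose two classes share one context model (label-free null)."""
    outdir = tmp_path_factory.mktemp("bench_null")
    spec = dc.SyntheticSpec(
        n_contigs=1, contig_length=40_000, n_drivers=100, n_passengers=300,
        driver_context=dc.markov_uniform(),
        passenger_context=dc.markov_uniform(),
        seed=12,
    )
    genome_path, mutations, descriptive = dc.make_benchmark(spec, outdir)
    return dc.open_genome(genome_path), mutations, descriptive


@pytest.fixture
def rng():
    return np.random.default_rng(0)
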