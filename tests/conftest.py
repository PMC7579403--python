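import pytest

from potn import model as mdl
from potn import synthetic as syn

BENCHMARK_SEED = 20260101


@pytest.fixture(scope="session")
def benchmark():
    """Strong-signal benchmark bundle shared across the suite."""
    return syn.make_benchmark(BENCHMARK_SEED)


@pytest.fixture(scope="session")
def full_model(benchmark):
    """Model trained on the benchmark with external columns (C tuned by LOO)."""
    return mdl.fit_potn(benchmark.train, external=benchmark.external)


@pytest.fixture(scope="session")
def core_model(benchmark):
    """Core-feature model (no externals), fixed C to keep the suite fast."""
    return mdl.fit_potn(benchmark.train, config=mdl.SvmConfig(C=1.0))


@pytest.fixture(scope="session")
def benchmark_fasta(benchmark, tmp_path_factory):
    from potn.peptide_io import write_fasta

    path = tmp_path_factory.mktemp("bench") / "proteins.fa"
    write_fasta(benchmark.proteins, path)
    return path
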