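import pytest
from hypothesis import HealthCheck, settings

from rarescan.io import write_fasta, write_gene_table, write_tsv
from rarescan.simulate import SyntheticClusterSpec, generate_cluster_set

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark_set():
    """Default three-species synthetic cluster benchmark (clean background)."""
    return generate_cluster_set(SyntheticClusterSpec(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def benchmark_dir(benchmark_set, tmp_path_factory):
    """Benchmark written to disk: per-species FASTA, gene table, truth table."""
    d = tmp_path_factory.mktemp("benchmark")
    for sp, seq in sorted(benchmark_set.sequences.items()):
        write_fasta([seq], d / f"{sp}.fasta")
    write_gene_table(benchmark_set.genes, d / "genes.tsv")
    write_tsv(benchmark_set.truth, d / "truth.tsv")
    return d
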