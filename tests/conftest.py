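import pytest

from kinascade import family, seqio, simulate
from kinascade.motifs import builtin_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


SMALL_CONFIG = dict(
    mapk=5,
    mapkk=2,
    mekk=3,
    raf=12,
    zik=2,
    decoy_random=20,
    decoy_near_miss=5,
    n_chromosomes=4,
    tandem_pair_count=2,
    cluster_spec=(("RAF", 3),),
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One small simulated dataset shared across the suite."""
    out = tmp_path_factory.mktemp("sim")
    config = simulate.SimulationConfig(**SMALL_CONFIG)
    fasta, gff, manifest = simulate.simulate_proteome(config, out)
    return {"config": config, "fasta": fasta, "gff": gff, "manifest": manifest}


@pytest.fixture(scope="session")
def small_records(small_sim):
    return seqio.read_fasta(small_sim["fasta"])


@pytest.fixture(scope="session")
def small_gene_models(small_sim):
    return seqio.read_gff3(small_sim["gff"])


@pytest.fixture(scope="session")
def small_inventory(small_records, small_gene_models):
    table, summary = family.run_inventory(small_records, small_gene_models)
    return table, summary
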