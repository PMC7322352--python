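import numpy as np
import pytest

from mrequant.catalog import build_mre_catalog, load_utr_annotation, read_motif_table
from mrequant.simdata import SimConfig, simulate_all


SMALL_CFG = dict(
    n_genes=8,
    n_families=10,
    families_per_gene=3,
    n_per_group=3,
    utr_length=(600, 900),
    mu=10.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small ground-truthed synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("smallsim")
    cfg = SimConfig(**SMALL_CFG)
    sim = simulate_all(cfg, outdir)
    sim["cfg"] = cfg
    sim["outdir"] = outdir
    return sim


@pytest.fixture(scope="session")
def small_catalog(small_sim):
    utrs = load_utr_annotation(small_sim["bed"], small_sim["fasta"])
    motifs = read_motif_table(small_sim["motifs"])
    return utrs, motifs, build_mre_catalog(utrs, motifs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
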