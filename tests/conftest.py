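import numpy as np
import pandas as pd
import pytest

from halotribes import SimParams, generate_pangenome


@pytest.fixture(scope="session")
def small_params():
    return SimParams(
        n_core_tribes=80,
        n_genus_tribes={"Haloferax": 25, "Haloarcula": 25},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return generate_pangenome(small_params)


@pytest.fixture(scope="session")
def quiet_params():
    """No score noise, no cross-tribe decoy pairs: the noiseless regime."""
    return SimParams(
        n_core_tribes=80,
        n_genus_tribes={"Haloferax": 25, "Haloarcula": 25},
        score_noise_sd=0.0,
        decoy_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def quiet_truth(quiet_params):
    return generate_pangenome(quiet_params)


@pytest.fixture()
def toy_genes():
    """Hand-built annotation table: 2 genera, 4 genomes, 10 genes."""
    rows = [
        ("a1", "A_g1", "GenusA", "cellulase family protein", "G", 300),
        ("a2", "A_g1", "GenusA", "hypothetical protein", "", 200),
        ("a3", "A_g2", "GenusA", "cellulase family protein", "GT", 310),
        ("a4", "A_g2", "GenusA", "TATA-binding protein", "K", 180),
        ("b1", "B_g1", "GenusB", "cellulase family protein", "G", 305),
        ("b2", "B_g1", "GenusB", "histidine kinase", "T", 400),
        ("b3", "B_g1", "GenusB", "hypothetical protein", "", 150),
        ("b4", "B_g2", "GenusB", "TATA-binding protein", "K", 185),
        ("b5", "B_g2", "GenusB", "histidine kinase", "T", 410),
        ("b6", "B_g2", "GenusB", "Cellulase, family 5", "G", 280),
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "genome_id", "genus_id", "product", "cog", "length_aa"]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
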