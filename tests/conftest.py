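import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import capcensus as cc

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_design(genotypes=("WT", "KO"), treatments=("UT", "starved"),
                n_replicates=2, experiment_id="toy"):
    rows = [
        dict(channel_id=f"{g}_{t}_r{r}", genotype=g, treatment=t, replicate=r,
             experiment_id=experiment_id)
        for g in genotypes for t in treatments
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def make_annotations(protein_ids, compartment="cytosol", known_fluxer=False,
                     histone=False, molar_mass=5e4):
    n = len(protein_ids)
    return cc.validate_annotations(pd.DataFrame(
        {
            "compartment": [compartment] * n,
            "golgi_class": ["not_golgi" if compartment != "Golgi" else "membrane"] * n,
            "tm_count": [0 if compartment != "Golgi" else 1] * n,
            "known_fluxer": [known_fluxer] * n,
            "histone": [histone] * n,
            "molar_mass": [molar_mass] * n,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    ))


def random_experiment(rng, n_proteins=10, n_replicates=2, log2=False):
    design = make_design(n_replicates=n_replicates)
    vals = rng.uniform(1.0, 100.0, size=(n_proteins, len(design)))
    intensity = pd.DataFrame(
        vals, index=[f"P{i:03d}" for i in range(n_proteins)],
        columns=design["channel_id"].tolist(),
    )
    return cc.QuantExperiment(intensity=intensity, design=design,
                              normalized=log2, log2=log2)


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests (seed fixed)."""
    cfg = cc.SimulationConfig(seed=20230927)
    exp, ann, truth = cc.simulate_quant(cfg)
    return cfg, exp, ann, truth
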