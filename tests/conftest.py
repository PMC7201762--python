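import numpy as np
import pandas as pd
import pytest

from smokesig.simulate import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small planted study shared across module tests (70/30 cohort)."""
    cfg = SimulationConfig(
        n_current=70,
        n_never=30,
        n_probes=300,
        n_genes=200,
        n_signature=20,
        n_dcs_pairs=10,
        ppi_n_proteins=120,
        rng_seed=11,
    )
    return generate_study(cfg, include_validation=True)


@pytest.fixture(scope="session")
def signature_annotation():
    from smokesig.io import load_signature_annotation

    return load_signature_annotation()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_metadata(sample_ids, statuses):
    """Complete clinical metadata for the given sample ids."""
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "smoking_status": statuses,
            "age": [60] * n,
            "gender": ["female"] * n,
            "stage": ["I"] * n,
            "vital_status": ["alive"] * n,
            "survival_days": [1000] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
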