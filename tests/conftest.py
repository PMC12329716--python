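import numpy as np
import pandas as pd
import pytest

from redoxomics.cleaning import FeatureMeta, FeatureTable
from redoxomics.pathways import GeneCatalog
from redoxomics.synth import SynthConfig, default_pathway_definitions


@pytest.fixture(scope="session")
def pathway_defs():
    return default_pathway_definitions()


@pytest.fixture()
def small_table():
    """4 features x 6 samples with two perfectly correlated rows."""
    rng = np.random.default_rng(7)
    base = rng.uniform(1e5, 1e6, 6)
    data = pd.DataFrame(
        {
            "F1": base,
            "F2": base * 0.3,          # exact fragment of F1
            "F3": rng.uniform(1e5, 1e6, 6),
            "F4": rng.uniform(1e5, 1e6, 6),
        },
        index=[f"s{i}" for i in range(6)],
    ).T
    return FeatureTable(data)


@pytest.fixture()
def small_meta():
    return [
        FeatureMeta("F1", mz=400.2005, rt=5.000,
                    ms2_fragments=(120.0101, 163.0601, 250.1)),
        FeatureMeta("F2", mz=163.0605, rt=5.002),
        FeatureMeta("F3", mz=300.15, rt=5.004),
        FeatureMeta("F4", mz=500.25, rt=9.0),
    ]


@pytest.fixture(scope="session")
def tiny_catalog():
    return GeneCatalog(pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "g4"],
        "mag_id": ["M1", "M1", "M2", "M2"],
        "ko": ["K00001", "K00003", "K00001", ""],
        "length_bp": [1000, 2000, 500, 1500],
    }))


@pytest.fixture(scope="session")
def default_synth_config():
    return SynthConfig(seed=1)
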