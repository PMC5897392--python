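import logging

import numpy as np
import pandas as pd
import pytest

from liverqtl.config import SimulationConfig
from liverqtl import simulate

logging.getLogger("liverqtl").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Four small studies over a 400-variant panel; strong planted effects."""
    return SimulationConfig(
        n_variants=400,
        n_genes=12,
        samples_per_study=(60, 50, 60, 30),
        n_primary_effects=5,
        n_secondary_effects=2,
        effect_size_sd=1.0,
        missing_rate=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate.simulate_study_set(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_genotype_frame(dosages: np.ndarray, chrom: str = "1", start_pos: int = 1000):
    """Helper: wrap a raw dosage array into a GenotypeMatrix."""
    from liverqtl.containers import GenotypeMatrix

    n, v = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start_pos + np.arange(v) * 100,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"v{j + 1}" for j in range(v)], name="variant"),
    )
    dos = pd.DataFrame(
        dosages,
        index=pd.Index([f"s{i + 1}" for i in range(n)], name="sample"),
        columns=variants.index,
    )
    return GenotypeMatrix(dos, variants)
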