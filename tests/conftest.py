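import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ploidysig import (
    ExpressionMatrix,
    SampleSheet,
    SynthConfig,
    generate_cross_species_dataset,
    generate_two_condition_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    """Fast generator settings used by most integration-style tests."""
    return SynthConfig(n_genes=600, reps_per_condition=3, seed=42)


@pytest.fixture(scope="session")
def cross_dataset(small_config):
    return generate_cross_species_dataset(small_config)


@pytest.fixture(scope="session")
def two_condition_dataset(small_config):
    return generate_two_condition_dataset(small_config)


@pytest.fixture()
def tiny_matrix():
    """Hand-sized matrix with a reciprocal 2-species x 2-tissue design."""
    rng = np.random.default_rng(0)
    genes = [f"G{i:03d}" for i in range(40)]
    samples, rows = [], []
    data = {}
    for species, tissue, ploidy in [
        ("HS", "heart", "polyploid"), ("HS", "liver", "diploid"),
        ("MM", "heart", "diploid"), ("MM", "liver", "polyploid"),
    ]:
        for rep in (1, 2, 3):
            sid = f"{species}_{tissue}_r{rep}"
            data[sid] = rng.normal(8, 1, len(genes))
            rows.append((sid, species, tissue, ploidy, rep))
            samples.append(sid)
    matrix = ExpressionMatrix(pd.DataFrame(data, index=genes))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "species", "tissue", "ploidy_class",
                       "replicate"]))
    return matrix, sheet
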