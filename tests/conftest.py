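import numpy as np
import pandas as pd
import pytest

from subpathsig import FeatureSet, SimulationConfig, generate_cohorts


def small_config(**overrides) -> SimulationConfig:
    """A fast, small study used where full scale is unnecessary."""
    fields = dict(
        n_cohorts=3,
        n_training=2,
        samples_per_cohort=120,
        n_genes=200,
        planted_set_size=8,
        n_decoy_pathways=5,
        n_cell_lines=40,
        seed=11,
    )
    fields.update(overrides)
    return SimulationConfig(**fields)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohorts(small_config())


@pytest.fixture()
def toy_expression() -> pd.DataFrame:
    """5 genes x 3 samples with distinct values per sample."""
    rng = np.random.default_rng(3)
    vals = rng.normal(6.0, 1.0, size=(5, 3))
    return pd.DataFrame(vals, index=list("abcde"), columns=["s1", "s2", "s3"])


@pytest.fixture()
def toy_features() -> list[FeatureSet]:
    return [
        FeatureSet(id="path:1_1", level="subpathway", genes=frozenset("ab"), parent="path:1"),
        FeatureSet(id="path:1", level="pathway", genes=frozenset("abc"), parent=""),
        FeatureSet(id="c", level="gene", genes=frozenset("c")),
    ]
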