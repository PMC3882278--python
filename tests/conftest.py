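import numpy as np
import pandas as pd
import pytest

from mirenrich import ExpressionDataset, OutcomeLabels, SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small planted study: fast, strong signal, three algorithms."""
    return SimulationConfig(
        n_genes=300,
        n_samples_pos=12,
        n_samples_neg=12,
        n_mirnas=20,
        n_planted=3,
        regulon_size=25,
        effect_size=1.5,
        algorithm_sensitivity=0.8,
        algorithm_fp_rate=0.1,
        seed=17,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]], index=["gA", "gB"], columns=["s1", "s2"]
    )
    return ExpressionDataset(frame)


def make_dataset(values, genes=None, samples=None) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples))


def make_labels(pos, neg) -> OutcomeLabels:
    status = {s: "relapse_pos" for s in pos}
    status.update({s: "relapse_neg" for s in neg})
    return OutcomeLabels(status)
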