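import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_matrix():
    """4 genes x 4 samples with a clean anchor reversal in the TFP pair."""
    return pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0, 9.0],
            "s2": [2.0, 6.0, 3.0, 8.0],
            "s3": [7.0, 5.0, 2.0, 9.0],
            "s4": [8.0, 6.0, 3.0, 7.0],
        },
        index=["ERG", "REF1", "REF2", "REF3"],
    )


@pytest.fixture
def tiny_labels():
    return pd.Series(
        ["TFN", "TFN", "TFP", "TFP"], index=["s1", "s2", "s3", "s4"], name="label"
    )


def random_expression(rng, n_genes=12, n_samples=8, prefix="g"):
    values = rng.lognormal(mean=2.0, sigma=1.0, size=(n_genes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
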