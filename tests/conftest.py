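import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plantlnc import LabeledDataset, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def pipeline_dataset() -> LabeledDataset:
    """1000 lncRNA-like + 1000 mRNA-like transcripts, 200-800 nt,
    feature-extracted with the builtin fold backend.

    Session-scoped: shared by the end-to-end and redundancy tests, which
    both exercise this one simulated corpus.
    """
    return simulate_dataset(
        1000, 1000, seed=42, length_range=(200, 800), fold_backend="builtin"
    )


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """200 + 200 short transcripts for cheaper model-level tests."""
    return simulate_dataset(
        200, 200, seed=7, length_range=(200, 400), fold_backend="builtin"
    )
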