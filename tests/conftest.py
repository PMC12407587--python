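import numpy as np
import pytest

from doppelscan.data_model import AbundanceTable, SampleLabels
from doppelscan.simulate import InjectionSpec, SimConfig, generate_table, inject_doppelgangers


@pytest.fixture
def toy_table() -> AbundanceTable:
    """4 samples x 5 features counts table with two near-identical cases."""
    values = np.array(
        [
            [10.0, 5.0, 0.0, 3.0, 2.0],
            [11.0, 5.0, 0.0, 3.0, 2.0],  # near-duplicate of row 0
            [1.0, 9.0, 6.0, 0.0, 4.0],
            [0.0, 8.0, 7.0, 1.0, 4.0],
        ]
    )
    return AbundanceTable(("s1", "s2", "s3", "s4"), ("f1", "f2", "f3", "f4", "f5"), values)


@pytest.fixture
def toy_labels() -> SampleLabels:
    return SampleLabels(
        {"s1": "case", "s2": "case", "s3": "control", "s4": "control"},
        case_label="case",
    )


def random_table(rng: np.random.Generator, n_samples: int, n_features: int) -> AbundanceTable:
    values = rng.integers(0, 50, size=(n_samples, n_features)).astype(float)
    # avoid all-zero rows / constant rows so correlations are defined
    values[:, 0] += np.arange(n_samples) + 1
    return AbundanceTable(
        tuple(f"s{i:02d}" for i in range(n_samples)),
        tuple(f"f{j:02d}" for j in range(n_features)),
        values,
    )


def random_labels(rng: np.random.Generator, table: AbundanceTable) -> SampleLabels:
    n = table.n_samples
    n_case = int(rng.integers(1, n))
    which = rng.permutation(n)
    lab = {
        s: ("case" if i in set(which[:n_case]) else "control")
        for i, s in enumerate(table.sample_ids)
    }
    return SampleLabels(lab, case_label="case")


@pytest.fixture(scope="session")
def injected_dataset():
    """Medium synthetic dataset with injected doppelganger pairs (shared)."""
    cfg = SimConfig(n_case=50, n_control=50, n_features=300, seed=42)
    table, labels, differential = generate_table(cfg)
    table, labels, injected = inject_doppelgangers(
        table, labels, InjectionSpec(n_pairs=5, noise_sd=0.05, seed=43)
    )
    return table, labels, differential, injected
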