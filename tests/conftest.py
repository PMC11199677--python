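import numpy as np
import pandas as pd
import pytest

from methorigin import LabelledDataset, OmicsMatrix, generate_methylation


@pytest.fixture(scope="session")
def default_cohort():
    """The desk-scale default cohort: 6 classes x 100 samples, 5,000 CpGs,
    50 planted markers per class, delta = 0.3."""
    return generate_methylation(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort for classifier/evaluation tests."""
    return generate_methylation(
        n_classes=6, n_per_class=60, n_features=1000, n_markers_per_class=20,
        delta=0.3, seed=11,
    )


@pytest.fixture()
def toy_dataset():
    """A hand-sized labelled dataset: 8 features x 12 samples, 3 classes."""
    rng = np.random.default_rng(5)
    values = rng.uniform(0.05, 0.95, size=(8, 12))
    frame = pd.DataFrame(
        values,
        index=[f"cg{i:03d}" for i in range(8)],
        columns=[f"s{i:02d}" for i in range(12)],
    )
    labels = pd.Series(
        ["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=frame.columns, name="label"
    )
    return LabelledDataset(OmicsMatrix(frame, domain="beta"), labels)


def random_labelled(rng, n_features, n_samples, n_classes=3):
    """Random beta-domain labelled dataset with balanced-ish labels."""
    values = rng.uniform(0.0, 1.0, size=(n_features, n_samples))
    frame = pd.DataFrame(
        values,
        index=[f"cg{i:04d}" for i in range(n_features)],
        columns=[f"s{i:04d}" for i in range(n_samples)],
    )
    labels = pd.Series(
        [f"K{i % n_classes}" for i in range(n_samples)], index=frame.columns
    )
    return LabelledDataset(OmicsMatrix(frame, domain="beta"), labels)
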