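import numpy as np
import pytest

from pepbench.datasets import PeptideDataset, SequenceRecord, generate_synthetic_dataset


def make_dataset(*sequences: str, labels=None, name="toy") -> PeptideDataset:
    """Build a dataset from raw sequences with default alternating labels."""
    if labels is None:
        labels = [i % 2 for i in range(len(sequences))]
    return PeptideDataset(
        name,
        [SequenceRecord(f"s{i}", seq, lab) for i, (seq, lab) in enumerate(zip(sequences, labels))],
    )


@pytest.fixture
def toy_dataset() -> PeptideDataset:
    return make_dataset("ACDEFGHIKL", "MNPQRSTVWY", "AAACCCDDDE", "KKRRKKRRKK")


@pytest.fixture
def biased_dataset() -> PeptideDataset:
    return generate_synthetic_dataset(
        n=80, imbalance=0.5, length_range=(15, 40), bias_residues=("K", "R"),
        bias_strength=0.4, seed=11,
    )


class ThresholdStubClassifier:
    """Deterministic probabilistic classifier for harness tests.

    Predicts P(class=1) as the sigmoid-free normalised rank of the first
    feature relative to the training-set class means: cheap, deterministic
    and dependent on the training data, which is all the CV tests need.
    """

    def fit(self, features: np.ndarray, classes: np.ndarray) -> None:
        x = features[:, 0]
        self.mid_ = (x[classes == 1].mean() + x[classes == 0].mean()) / 2.0
        self.scale_ = max(float(x.std()), 1e-9)

    def predict_probability(self, features: np.ndarray) -> np.ndarray:
        z = (features[:, 0] - self.mid_) / self.scale_
        return 1.0 / (1.0 + np.exp(-z))


def stub_factory(seed: int) -> ThresholdStubClassifier:
    return ThresholdStubClassifier()
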