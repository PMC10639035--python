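import numpy as np
import pytest

from oriseq import SyntheticConfig, generate_synthetic_dataset
from oriseq.neural import ArchConfig, TrainConfig
from oriseq.pipeline import PipelineConfig


def small_arch(**overrides) -> ArchConfig:
    """Desk-scale architecture: six branches, small filters/GRUs."""
    kw = dict(
        conv_branches=tuple((8, k) for k in (2, 4, 6, 8, 10, 12)),
        gru_units=(6, 8),
        attention_dim=12,
        dense_units=16,
        pool=10,
    )
    kw.update(overrides)
    return ArchConfig(**kw)


def fast_train(**overrides) -> TrainConfig:
    kw = dict(epochs=5, batch_size=128, seed=0)
    kw.update(overrides)
    return TrainConfig(**kw)


def fast_pipeline_config(seed=0, **overrides) -> PipelineConfig:
    kw = dict(
        arch=small_arch(),
        train=fast_train(),
        classifier_params={"n_trees": 200},
        seed=seed,
    )
    kw.update(overrides)
    return PipelineConfig(**kw)


def encoder_only_config(seed=0, **overrides) -> PipelineConfig:
    """Classical encoders + classifier, no neural extractor/selection."""
    kw = dict(
        use_dl=False,
        use_selection=False,
        classifier_params={"n_trees": 150},
        seed=seed,
    )
    kw.update(overrides)
    return PipelineConfig(**kw)


@pytest.fixture(scope="session")
def learnable_dataset():
    """Strong two-signal benchmark (GC skew + planted motif)."""
    return generate_synthetic_dataset(
        SyntheticConfig(n_per_class=250, gc_skew_shift=0.1, motif_rate=0.8, seed=11)
    )


@pytest.fixture(scope="session")
def random_sequences():
    """200 random ACGT sequences with lengths spread over 20..300."""
    rng = np.random.default_rng(42)
    seqs = []
    for _ in range(200):
        L = int(rng.integers(20, 301))
        seqs.append("".join(rng.choice(list("ACGT"), size=L)))
    return seqs


@pytest.fixture(scope="session")
def trained_extractor(learnable_dataset):
    """One session-wide trained extractor for feature-level tests."""
    from oriseq.neural import NeuralSequenceExtractor

    ext = NeuralSequenceExtractor(arch=small_arch(), train=fast_train(epochs=6))
    ext.fit(learnable_dataset.sequences(), learnable_dataset.labels())
    return ext
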