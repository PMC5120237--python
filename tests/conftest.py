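import numpy as np
import pandas as pd
import pytest

from perspect.message_store import Message, MessageLibrary, MessageSource, ReadinessStage
from perspect.recommender_core import FactorModelConfig, fit_bpmf
from perspect.synthetic_data import GeneratorConfig, RatingDataset, generate_library, generate_ratings

ALL_STAGES = frozenset(ReadinessStage)


def make_message(mid, stages=ALL_STAGES, tags=(), source=MessageSource.EXPERT, text=None):
    return Message(
        id=mid,
        text=text or f"message {mid}",
        source=source,
        stages=frozenset(stages),
        tags=frozenset(tags),
    )


@pytest.fixture
def tiny_library():
    return MessageLibrary(
        [
            make_message("m1", {ReadinessStage.NOT_THINKING, ReadinessStage.THINKING}, {"MOTIVATIONAL_CONTENT"}),
            make_message("m2", {ReadinessStage.THINKING}, {"BEHAVIORAL_TREATMENT"}, MessageSource.PEER),
            make_message("m3", {ReadinessStage.ALREADY_QUIT}),
        ]
    )


@pytest.fixture(scope="session")
def canonical_library():
    """Synthetic 261-message library with the canonical tag composition."""
    return generate_library()


@pytest.fixture(scope="session")
def small_dataset():
    """30 users x 20 ratings over 25 messages: enough for the protocol."""
    data, truth = generate_ratings(
        GeneratorConfig(n_users=30, n_messages=25, ratings_per_user=20, seed=7)
    )
    return data, truth


@pytest.fixture(scope="session")
def small_bpmf(small_dataset):
    data, _ = small_dataset
    return fit_bpmf(data, FactorModelConfig(latent_dim=2, n_samples=30, burn_in=20, seed=3))


def constant_dataset(value=3, n_users=6, n_messages=6):
    """Fully observed matrix with every rating equal to *value*."""
    rows = [
        {"user": f"u{i}", "message": f"m{j}", "rating": value}
        for i in range(n_users)
        for j in range(n_messages)
    ]
    return RatingDataset(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
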