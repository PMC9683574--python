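import numpy as np
import pytest

import shapaal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Small hand-made 2-class dataset."""
    return shapaal.TimeSeriesDataset(
        series=np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0], [0.5, 1.0, 1.5], [1.5, 1.0, 0.5]]),
        labels=np.array([1, 2, 1, 2]),
        name="tiny_TRAIN",
        role="train",
    )


@pytest.fixture
def separable_pair():
    """Noiseless-ish, well-separated synthetic train/test pair (short series)."""
    spec = shapaal.SyntheticSpec(
        n_train=24, n_test=40, length_t=24, n_classes=2, noise_sd=0.2, seed=7, name="sep"
    )
    train, test, truth = shapaal.generate(spec)
    return train, test, truth


@pytest.fixture
def mislabeled_pair():
    spec = shapaal.SyntheticSpec(
        n_train=60, n_test=120, length_t=96, n_classes=2, noise_sd=0.5,
        mislabel_fraction=0.2, seed=3, name="mis",
    )
    return shapaal.generate(spec)


@pytest.fixture
def fast_model_config():
    return shapaal.ResNetConfig(n_blocks=2, epochs=30, filters_per_block=6, seed=0)


def random_game(n_players: int, seed: int):
    """A random transferable-utility game with i.i.d. coalition worths."""
    rng = np.random.default_rng(seed)
    table = {}

    def value_fn(psi):
        if psi not in table:
            table[psi] = float(rng.normal()) if psi else 0.0
        return table[psi]

    return shapaal.CoalitionGame(n_players=n_players, value_fn=value_fn)
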