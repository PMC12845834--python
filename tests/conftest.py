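import numpy as np
import pytest

import ntfold as nf
from ntfold.train_eval import Checkpoint, TrainConfig, evaluate_dataset, predict
from ntfold.encoder import EncoderParams
from ntfold.refiner import RefinementParams

HAIRPIN_MUT = nf.FamilySpec(family="hairpin", mutation_rate=0.02)


@pytest.fixture(scope="session")
def hairpin_train_set():
    return nf.make_dataset(500, {"hairpin": 1.0}, {"hairpin": HAIRPIN_MUT}, seed=11)


@pytest.fixture(scope="session")
def hairpin_test_set():
    return nf.make_dataset(100, {"hairpin": 1.0}, {"hairpin": HAIRPIN_MUT}, seed=12)


@pytest.fixture(scope="session")
def trained_checkpoint(hairpin_train_set):
    """Default tiny model (d=64, H=4, U-Net depth 2) trained on 500 hairpins."""
    return nf.train(hairpin_train_set, cfg=TrainConfig(epochs=30, seed=7))


@pytest.fixture(scope="session")
def untrained_checkpoint():
    rng = np.random.default_rng(7)
    return Checkpoint(
        encoder=EncoderParams(rng=rng),
        refiner=RefinementParams(rng=rng),
        train_config=TrainConfig(seed=7),
    )


def mean_f1(ckpt, test_set):
    records = [(predict(seq, ckpt)[0], truth) for seq, truth in test_set]
    return evaluate_dataset(records)[1]["f1"]
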