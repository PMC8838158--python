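import numpy as np
import pytest

from ecgcnn import datapath, synthetic, training


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """40 train + 10 test beats per class: enough signal, fast to make."""
    cfg = synthetic.GeneratorConfig(seed=11)
    return synthetic.generate_dataset(40, 10, cfg)


@pytest.fixture(scope="session")
def trained(small_dataset):
    """Weights trained briefly on the small dataset, plus their calibrated form."""
    cfg = training.TrainConfig(epochs=15, seed=99)
    w, report = training.train(
        small_dataset.train_x, small_dataset.train_y, cfg,
        val_x=small_dataset.test_x, val_y=small_dataset.test_y,
    )
    fmt = datapath.FixedPointFormat()
    wc = training.calibrate_weights(w, small_dataset.train_x, fmt)
    return {"weights": w, "calibrated": wc, "report": report, "fmt": fmt}
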