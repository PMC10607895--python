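import numpy as np
import pytest

from ingseg.attnet import AttNetConfig, build_attnet
from ingseg.synthetic import default_class_specs, generate_dataset
from ingseg.taxonomy import balanced_taxonomy
from ingseg.training import TrainConfig, train_slm

TINY_CHANNELS = (8, 16, 16, 32, 32, 64, 64)  # Table-1 schedule / 8


@pytest.fixture(scope="session")
def toy_tax():
    """Chain taxonomy Crop -> Fruits -> pome -> apple, C = (1, 1, 1, 1)."""
    from ingseg.taxonomy import build_taxonomy

    return build_taxonomy(
        [(1, "Crop", None), (2, "Fruits", "Crop"), (3, "pome", "Fruits"),
         (4, "apple", "pome")]
    )


@pytest.fixture(scope="session")
def tax8():
    return balanced_taxonomy((2, 4, 8, 8))


@pytest.fixture(scope="session")
def class_specs8():
    return default_class_specs(8, variants_per_class=4, images_per_variant=9,
                               seed=0)


@pytest.fixture(scope="session")
def dataset8(class_specs8, tax8):
    """288-image, 8-class synthetic dataset at 64 x 64 with an 80/20 split."""
    return generate_dataset(class_specs8, tax8, split_seed=0, image_seed=0,
                            size=64)


@pytest.fixture(scope="session")
def tiny_config():
    return AttNetConfig(variant="1", num_classes=8, input_size=64,
                        channels=TINY_CHANNELS, seed=0)


@pytest.fixture(scope="session")
def trained_slm(dataset8, tiny_config):
    """Tiny AttNet(1) trained for the full 30 epochs; shared across tests."""
    model = build_attnet(tiny_config)
    result = train_slm(
        model,
        dataset8.images[dataset8.train_idx],
        dataset8.leaf_labels[dataset8.train_idx],
        TrainConfig(epochs=30, seed=0),
    )
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
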