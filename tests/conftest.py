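import numpy as np
import pytest

import genecam as g


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three small, well-separated classes; quick to cross-validate."""
    spec = g.default_spec(
        11, n_genes=90, n_classes=3, samples_per_class=(10, 9, 8), n_markers_per_class=5
    )
    return g.generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_configs():
    """Small image and network so one training run takes seconds."""
    pconfig = g.PreprocessConfig(image_length=32)
    cconfig = g.CNNConfig(
        n_classes=3, image_length=32, conv_filters=(8, 16, 16), fc_sizes=(32, 16, 8)
    )
    tconfig = g.TrainConfig(epochs=25, folds=3, batch_size=8, seed=11)
    return pconfig, cconfig, tconfig


@pytest.fixture(scope="session")
def tiny_cv(tiny_dataset, tiny_configs):
    pconfig, cconfig, tconfig = tiny_configs
    return g.cross_validate(tiny_dataset, pconfig, cconfig, tconfig)


def class_indices(dataset, images):
    names = sorted(dataset.labels.unique())
    return np.array([names.index(dataset.labels[img.sample_id]) for img in images])
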