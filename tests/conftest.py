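"""Shared fixtures; trained models are session-scoped since training is the
expensive step and several end-to-end analyses reuse the same model."""

import numpy as np
import pytest

from vstain.experiments import (MEMBRANE_MODEL_CONFIG, membrane_training_scene,
                                nucleus_training_scene, train_channel_model)


@pytest.fixture(scope="session")
def membrane_model():
    """Membrane staining model trained on 200 synthetic 64x64 pairs."""
    model, history = train_channel_model("membrane", n_train=200, seed=7,
                                         config=MEMBRANE_MODEL_CONFIG)
    assert np.isfinite(history.train_loss).all()
    return model


@pytest.fixture(scope="session")
def nucleus_model():
    """Nucleus staining model trained on 150 synthetic 64x64 pairs."""
    model, _ = train_channel_model("nucleus", n_train=150, seed=21)
    return model


@pytest.fixture(scope="session")
def membrane_test_scenes():
    """Held-out pavement scenes (not in the membrane training seed range)."""
    return [membrane_training_scene(10_000 + i) for i in range(20)]


@pytest.fixture(scope="session")
def by2_test_scenes():
    """Held-out BY-2-style scenes with nucleus + membrane truth channels."""
    return [nucleus_training_scene(99_000 + i) for i in range(10)]


@pytest.fixture(scope="session")
def viability_results():
    """Fig 7 analog at the study's split: 900 train / 300 test per class,
    10 random-forest seeds, staining model trained on 300 crops."""
    from vstain.experiments import viability_comparison
    return viability_comparison(n_train_per_class=900, n_test_per_class=300,
                                seeds=range(10), seed=50_000, n_stain_pairs=300)
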