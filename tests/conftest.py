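import numpy as np
import pytest

from cropseg import engine, losses, model, scene, synth
from cropseg.estimator import PatchSegmenter


def make_scene(h=64, w=64, n_classes=4, seed=0):
    """Small fully-valid scene with random labels, for plumbing tests."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=(h, w)).astype(np.uint8)
    image = rng.normal(size=(4, h, w)).astype(np.float32)
    return scene.Scene(image, labels, np.ones((h, w), dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_patches():
    """Default synthetic study scene tiled into 64x64 patches, 8:1:1 split."""
    cfg = synth.SynthConfig(seed=7)
    sc = synth.generate_scene(cfg)
    patches = scene.filter_masked(scene.tile(sc, 64, 64))
    splits = scene.split(patches, scene.SplitSpec(seed=7))
    return patches, splits


@pytest.fixture(scope="session")
def scaled_study(study_patches):
    """Width-16 model trained on the study scene (the scaled learning run)."""
    patches, splits = study_patches
    result = engine.train(
        model.NetConfig.scaled(16), losses.LossConfig(),
        engine.TrainConfig(epochs=30, patience=20, seed=7),
        patches, splits)
    return patches, splits, result


@pytest.fixture(scope="session")
def overfit_study():
    """Wider model memorising 8 patches: the overfit sanity run."""
    cfg = synth.SynthConfig(seed=1)
    sc = synth.generate_scene(cfg)
    patches = scene.filter_masked(scene.tile(sc, 64, 64))[:8]
    X = np.stack([p.image for p in patches])
    y = np.stack([p.labels for p in patches])
    est = PatchSegmenter(base_width=32, epochs=30, batch_size=2, lr=0.001,
                         ce_weight=1.0, dice_weight=1.0, seed=1)
    est.fit(X, y)
    return est, X, y
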