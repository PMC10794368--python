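import numpy as np
import pytest

from vitalign.data import SyntheticSpec, generate
from vitalign.vit import ViTConfig, ViTModel


@pytest.fixture(scope="session")
def tiny_cfg() -> ViTConfig:
    # 16x16 images, 4 patches + class token, 2 blocks of 3 heads
    return ViTConfig(image_size=16, patch_size=8, channels=3, embed_dim=24,
                     depth=2, heads=3, mlp_ratio=2.0, dropout_rate=0.0)


@pytest.fixture()
def tiny_model(tiny_cfg) -> ViTModel:
    return ViTModel(tiny_cfg, n_classes=4, seed=0)


@pytest.fixture(scope="session")
def tiny_batch(tiny_cfg) -> np.ndarray:
    rng = np.random.default_rng(42)
    return rng.random((3, tiny_cfg.channels, tiny_cfg.image_size,
                       tiny_cfg.image_size))


@pytest.fixture(scope="session")
def small_dataset():
    """4 classes x (8 train + 4 test) 16px images; fast to train on."""
    return generate(SyntheticSpec(n_classes=4, image_size=16,
                                  train_per_class=8, test_per_class=4,
                                  seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 13-class benchmark at its default size."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def joint_trained(default_dataset):
    """Tiny backbone jointly trained on all 13 classes (shared, expensive)."""
    from vitalign.engine import TrainConfig, run_stage

    ds = default_dataset
    model = ViTModel(ViTConfig(), n_classes=ds.n_classes, seed=0)
    cfg = TrainConfig(epochs_per_stage=20, optimizer="adamw",
                      strategy="finetuning", learning_rate=1e-3, seed=0)
    run_stage(model, None, ds.train_images, ds.train_labels, cfg, 0)
    return model, ds
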