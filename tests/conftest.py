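import numpy as np
import pytest

from curriseg import (ArrayDataset, BackboneConfig, CurriculumSchedule,
                      RunConfig, SegmentationModel, generate_synthetic)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 synthetic 32x32 lesion images with exact masks."""
    return generate_synthetic(12, 32, seed=7)


@pytest.fixture(scope="session")
def tiny_pools(tiny_dataset):
    """(labeled, unlabeled, val) pools carved from the tiny dataset."""
    ds = tiny_dataset
    labeled = ArrayDataset(ds.images[:3], ds.masks[:3], ds.stems[:3])
    unlabeled = ArrayDataset(ds.images[3:9], None, ds.stems[3:9])
    val = ArrayDataset(ds.images[9:], ds.masks[9:], ds.stems[9:])
    return labeled, unlabeled, val


@pytest.fixture()
def tiny_config():
    """A 32x32 depth-2 run config small enough for per-test training."""
    return RunConfig(
        backbone=BackboneConfig(base_width=4, depth=2, embed_dim=8),
        schedule=CurriculumSchedule(stage1_epochs=1, patch_counts=(4, 16),
                                    trigger_epochs=(2, 4), total_epochs=4),
        resolution=32, seed=0, eval_every=2)


@pytest.fixture(scope="session")
def tiny_model():
    return SegmentationModel(BackboneConfig(base_width=4, depth=2,
                                            embed_dim=8), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
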