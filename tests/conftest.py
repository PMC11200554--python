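import numpy as np
import pytest

from cytovae.data_io import AnnotationRecord, Augmentation, AugmentationMode, extract_crop
from cytovae.synthetic import PopulationSpec, generate_population
from cytovae.vae import LossVariant, VAEConfig, train


@pytest.fixture(scope="session")
def small_population():
    """A small labelled synthetic population with 64px model crops."""
    spec = PopulationSpec(n_normal=120, n_abnormal=40, seed=12345)
    images, annotations, phenotypes = generate_population(spec)
    crops, labels = [], []
    for _, row in annotations.iterrows():
        rec = AnnotationRecord(
            row.image_id, int(row.center_x), int(row.center_y), str(row["class"])
        )
        crops.append(extract_crop(images[row.image_id], rec, crop_size=128))
        labels.append(rec.class_label)
    return {
        "images": images,
        "annotations": annotations,
        "phenotypes": phenotypes,
        "crops": np.asarray(crops),
        "labels": np.asarray(labels),
    }


@pytest.fixture(scope="session")
def smoke_state(small_population):
    """A briefly trained beta-TCVAE shared by training-dependent tests."""
    labels = small_population["labels"]
    crops = small_population["crops"]
    idx = np.flatnonzero(labels == "NILM")[:80]
    config = VAEConfig(
        latent_dim=8,
        beta=4.0,
        loss_variant=LossVariant.BETA_TCVAE,
        augmentation=Augmentation(mode=AugmentationMode.NONE),
        epochs=6,
        seed=7,
    )
    return train(crops[idx], config, labels=list(labels[idx]))
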