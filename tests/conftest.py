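import numpy as np
import pytest

from bodyregion import (
    Modality,
    PhantomSpec,
    TrainConfig,
    build_vocabulary,
    generate_study,
    preprocess_image,
    train,
)


@pytest.fixture(scope="session")
def mri_vocab():
    return build_vocabulary(Modality.MRI)


@pytest.fixture(scope="session")
def ct_vocab():
    return build_vocabulary(Modality.CT)


@pytest.fixture(scope="session")
def head_neck_phantom():
    """Two-region MRI phantom with two series in one frame of reference."""
    spec = PhantomSpec(
        modality="MRI",
        regions_present=[("head", 100.0), ("neck", 100.0)],
        slice_spacing_mm=10.0,
        transition_zone_mm=0.0,
        n_series=2,
        seed=7,
        patient_id="PX",
        study_uid="SX",
    )
    return generate_study(spec)


@pytest.fixture(scope="session")
def tiny_model(mri_vocab):
    """Compact classifier trained on a 3-class phantom subset; session-scoped."""
    rng = np.random.default_rng(11)
    inputs, labels = [], []
    for region in ("head", "chest", "knee"):
        spec = PhantomSpec(
            modality="MRI",
            regions_present=[(region, 100.0)],
            slice_spacing_mm=10.0,
            seed=int(rng.integers(2**31 - 1)),
            patient_id=f"P-{region}",
            study_uid=f"S-{region}",
        )
        phantom = generate_study(spec)
        for series in phantom.study.series:
            for im in series.images:
                inputs.append(preprocess_image(im.pixels))
                labels.append(phantom.truth[im.image_uid])
    cfg = TrainConfig(epochs=5, seed=3)
    return train(inputs, labels, mri_vocab, cfg)
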