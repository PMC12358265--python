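import numpy as np
import pytest

from glaucroi.synthetic import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """26-eye cohort at 32x32 with deep defects; shared across tests."""
    cfg = PhantomConfig(
        n_patients_healthy=8,
        n_patients_glaucoma=8,
        map_height=32,
        map_width=32,
        defect_depth_range=(0.5, 0.7),
        seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_models(small_cohort):
    """Healthy and glaucoma autoencoders trained once on the small cohort,
    reused by the reconstruction-error / segmentation / scoring tests."""
    from glaucroi.autoencoder import AEConfig, train_autoencoder

    c = small_cohort
    healthy = [(r.patient_id, c.enface[r.eye_id].values) for r in c.records if r.diagnosis == "healthy"]
    glaucoma = [(r.patient_id, c.enface[r.eye_id].values) for r in c.records if r.diagnosis == "glaucoma"]
    cfg = AEConfig(input_size=(32, 32), epochs=60, seed=7)
    h_model = train_autoencoder([v for _, v in healthy], cfg, "healthy", patient_ids=[p for p, _ in healthy])
    g_model = train_autoencoder([v for _, v in glaucoma], cfg, "glaucoma", patient_ids=[p for p, _ in glaucoma])
    return h_model, g_model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
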