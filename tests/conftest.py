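"""Shared fixtures: meshes, mappings, synthetic cohorts, and trained models.

The expensive fixtures (trained VAEs, the 300-scan cohort) are session-scoped
and shared between the unit tests and the end-to-end acceptance tests.  All
randomness is seeded; problem sizes are desk-scale stand-ins for the real
cohorts (icosphere meshes, 32 x 32 grids, a few thousand training frames).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from latentcortex.agepred import fc_feature_matrix, latent_fc
from latentcortex.grid import GridSequence, build_grid_mapping, to_grid
from latentcortex.synthetic import default_truth, make_mesh, simulate_cohort
from latentcortex.vae import VAEConfig, build_vae, encode, train_vae

#: Desk-scale training configuration: the architecture and optimizer of the
#: full model, with the KL weight rescaled to the smaller reconstruction term
#: (the loss sums squared error over ~1.2k valid cells here versus ~59k
#: cortical vertices at full scale; beta = 9 * 1220/59412 ~ 0.2 preserves the
#: balance between the two terms) and a faster learning rate suited to the
#: short 20-epoch schedule.
DESK_CONFIG = dict(seed=0, epochs=20, learning_rate=1e-3, beta=0.2)

TINY_CHANNELS = (8, 16, 32, 32, 32)


@pytest.fixture(scope="session")
def mesh3():
    return make_mesh(3)


@pytest.fixture(scope="session")
def mesh4():
    return make_mesh(4)


@pytest.fixture(scope="session")
def mapping32(mesh3):
    return build_grid_mapping(mesh3, (32, 32))


@pytest.fixture(scope="session")
def truth_k5(mesh3):
    return default_truth(mesh3, K=5, seed=0)


@pytest.fixture(scope="session")
def train_cohort_k5(mesh3, truth_k5):
    scans, table, manifest = simulate_cohort(
        mesh3, truth_k5, 10, T=200, tr_seconds=0.8, seed=1)
    return scans, table, manifest


def _train_on(scans, mapping, config):
    frames = np.concatenate([to_grid(ts, mapping).frames for ts in scans])
    seq = GridSequence(frames=frames, validity=mapping.validity)
    model = build_vae(config, mapping.grid_shape)
    model, curve = train_vae(model, seq, config)
    return model, curve


@pytest.fixture(scope="session")
def vae_k5(train_cohort_k5, mapping32):
    """VAE trained on the K=5 cohort (2,000 frames, 20 epochs, seed 0)."""
    scans, _, _ = train_cohort_k5
    model, curve = _train_on(scans, mapping32, VAEConfig(**DESK_CONFIG))
    return model, curve


@pytest.fixture(scope="session")
def k40_setup(mesh3, mapping32):
    """Richer cohort (K=40 networks) for the reconstruction-ordering test:
    the comparison of a 256-latent model against a rank-30 linear basis is
    informative only when the data holds more than 30 dimensions."""
    truth = default_truth(mesh3, K=40, seed=0)
    scans, _, _ = simulate_cohort(mesh3, truth, 10, T=200, tr_seconds=0.8, seed=1)
    heldout, _, _ = simulate_cohort(mesh3, truth, 3, T=100, tr_seconds=0.8, seed=99)
    model, curve = _train_on(scans, mapping32, VAEConfig(**DESK_CONFIG))
    return dict(truth=truth, scans=scans, heldout=heldout, model=model, curve=curve)


@pytest.fixture(scope="session")
def tiny_vae(mesh3, mapping32, truth_k5):
    """Small trained model (narrow channels, 32 latents) for Monte-Carlo
    convergence and checkpoint tests."""
    cfg = VAEConfig(n_latent=32, encoder_channels=TINY_CHANNELS,
                    epochs=4, learning_rate=1e-3, beta=0.2, seed=0)
    scans, _, _ = simulate_cohort(mesh3, truth_k5, 3, T=200, tr_seconds=0.8, seed=7)
    model, _ = _train_on(scans, mapping32, cfg)
    return model


@pytest.fixture(scope="session")
def latent_cohort300(mesh3, truth_k5, mapping32, vae_k5):
    """300-scan cohort encoded through the trained VAE: latent-FC features
    and ages, the input of the age-prediction protocols."""
    model, _ = vae_k5
    scans, table, _ = simulate_cohort(mesh3, truth_k5, 300, T=250,
                                      tr_seconds=0.8, seed=21)
    fcs = [latent_fc(encode(model, to_grid(ts, mapping32),
                            subject_id=ts.subject_id, age_weeks=ts.age_weeks))
           for ts in scans]
    F, ages = fc_feature_matrix(fcs)
    return F, ages


@pytest.fixture(scope="session")
def latent_cohort_null(mesh3, truth_k5, mapping32, vae_k5):
    """Cohort whose generative age effect is exactly zero (leakage guard)."""
    model, _ = vae_k5
    truth0 = dataclasses.replace(truth_k5, age_effect=np.zeros((5, 5)))
    scans, _, _ = simulate_cohort(mesh3, truth0, 150, T=250,
                                  tr_seconds=0.8, seed=22)
    fcs = [latent_fc(encode(model, to_grid(ts, mapping32),
                            age_weeks=ts.age_weeks))
           for ts in scans]
    F, ages = fc_feature_matrix(fcs)
    return F, ages
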