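"""Shared fixtures: small synthetic ensembles and one fully trained VAE.

The expensive fixture (`study_vae`) reproduces the package's reference
study conditions — a 2,000-frame, 50-residue CA-only trajectory with the
default VAE trained on the chronologically first half — and is shared
session-wide by the training/evaluation tests.
"""

from dataclasses import dataclass

import numpy as np
import pytest

import idpgen as ig


@pytest.fixture(scope="session")
def small_ensemble() -> ig.Ensemble:
    """20-residue, 30-frame CA trajectory with the default compaction drift."""
    return ig.generate_trajectory(ig.ChainSpec(n_residues=20, n_frames=30, seed=11))


@pytest.fixture(scope="session")
def backbone_ensemble() -> ig.Ensemble:
    """Full-backbone (N, CA, C, O) synthetic trajectory."""
    return ig.generate_trajectory(
        ig.ChainSpec(n_residues=10, n_frames=5, representation="backbone", seed=5)
    )


@dataclass
class StudyRun:
    """Everything produced by one reference training run."""

    ensemble: ig.Ensemble
    train: ig.FlatDataset
    test: ig.FlatDataset
    result: ig.TrainedModel
    reference: ig.Ensemble  # aligned heavy-atom test frames


# study conditions: 2,000 frames, 50 residues, first 50% trains the default
# VAE; 200 epochs ~ 3,200 Adam steps brings the optimizer to convergence at
# this training-set size.
STUDY_SEED = 2026
STUDY_EPOCHS = 200


def run_study(
    seed: int = STUDY_SEED,
    model_kind: str = "vae",
    epochs: int = STUDY_EPOCHS,
    n_frames: int = 2000,
    n_residues: int = 50,
) -> StudyRun:
    ensemble = ig.generate_trajectory(
        ig.ChainSpec(n_residues=n_residues, n_frames=n_frames, seed=seed)
    )
    aligned = ig.align_ensemble(ensemble)
    raw, amap = ig.flatten(aligned)
    train, test = ig.chronological_split(raw, 0.5, amap)
    if model_kind == "vae":
        config = ig.ModelConfig.vae_default(seed=seed + 1, epochs=epochs)
    else:
        config = ig.ModelConfig.ae_default(n_residues, seed=seed + 1, epochs=epochs)
    model = ig.ConformationalAutoencoder(
        train, config, topology=aligned.topology.heavy_subset()
    )
    result = model.fit()
    reference = ig.Ensemble(result.topology, ig.unflatten(test.raw()))
    return StudyRun(ensemble=ensemble, train=train, test=test, result=result, reference=reference)


@pytest.fixture(scope="session")
def study_vae() -> StudyRun:
    return run_study()


@pytest.fixture(scope="session")
def two_basin():
    """2-basin labelled ensemble (30 residues, 300 frames, 0.5 A noise)."""
    ensemble, labels = ig.generate_multibasin(
        ig.ChainSpec(n_residues=30, n_frames=300, basin_count=2, noise_sigma=0.5, seed=3)
    )
    return ensemble, labels


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
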