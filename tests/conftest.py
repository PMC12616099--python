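"""Shared fixtures: small phantom cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import mechage as mg


@pytest.fixture(scope="session")
def small_cohort():
    """60 healthy phantom subjects on a 16^3 grid with default ageing trends."""
    cfg = mg.PhantomConfig(grid_shape=(16, 16, 16), n_subjects=60, seed=0)
    atlas = mg.generate_atlas(cfg)
    vols, recs = mg.generate_cohort(cfg, "HC", atlas)
    return cfg, atlas, vols, recs


@pytest.fixture(scope="session")
def default_atlas():
    """Atlas at the reference 32^3 grid."""
    cfg = mg.PhantomConfig()
    return cfg, mg.generate_atlas(cfg)


@pytest.fixture(scope="session")
def trained_small(small_cohort):
    """A trained whole-brain predictor with its split (16^3, 60 subjects)."""
    cfg, atlas, vols, recs = small_cohort
    by_id = {v.subject_id: v for v in vols}
    ages = {r.subject_id: r.age for r in recs}
    split = mg.split_dataset(recs, 0.8, seed=0)
    tr = [by_id[i] for i in split.train_ids]
    te = [by_id[i] for i in split.test_ids]
    ytr = np.array([ages[i] for i in split.train_ids])
    yte = np.array([ages[i] for i in split.test_ids])
    predictor, log = mg.train_age_predictor(
        tr, ytr, mg.EncoderConfig(in_channels=2, embedding_dim=16),
        mg.TrainConfig(epochs=10, batch_size=16, seed=0))
    return predictor, log, (tr, te, ytr, yte)
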