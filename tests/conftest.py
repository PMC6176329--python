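"""Shared fixtures: a phantom-trained cascade reused across the suite."""

from types import SimpleNamespace

import numpy as np
import pytest

import spinecurve as sc
from spinecurve.cascade import save_model, train_cascade
from spinecurve.phantom import (
    generate_training_patches,
    make_background_sampler,
    phantom_pipeline_config,
)

TRAIN_ANGLES = [0, 5, 15, 30, 45, 15]


@pytest.fixture(scope="session")
def phantom_setup():
    """A 3-stage cascade trained on six phantoms spanning the angle range."""
    cfg = phantom_pipeline_config()
    train_specs = [
        sc.spec_for_angle(a, seed=100 + i) for i, a in enumerate(TRAIN_ANGLES)
    ]
    pos, neg = [], []
    for spec in train_specs:
        patches, labels = generate_training_patches(
            spec, 28, 56, window=cfg.features.window
        )
        pos.append(patches[labels == 1])
        neg.append(patches[labels == 0])
    sampler = make_background_sampler(train_specs, cfg.features.window)
    model = train_cascade(
        np.concatenate(pos),
        np.concatenate(neg),
        cfg.features,
        cfg.detector,
        neg_sampler=sampler,
        rng=np.random.default_rng(0),
    )
    return SimpleNamespace(cfg=cfg, model=model, train_specs=train_specs)


@pytest.fixture(scope="session")
def model_path(phantom_setup, tmp_path_factory):
    path = tmp_path_factory.mktemp("model") / "cascade.json"
    save_model(phantom_setup.model, path)
    return path
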