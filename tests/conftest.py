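"""Shared fixtures.

The expensive end-to-end artefact (hinge ensemble -> clustering -> sharded
dataset -> trained desk-scale autoencoder) is built once per session and
reused by every test that needs a trained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from afmstate.config import substream
from afmstate.dataset import build_dataset
from afmstate.fixtures import HingeSpec, make_hinge_ensemble
from afmstate.nn import ModelConfig, TrainConfig, build_model, train
from afmstate.simulate import ImageGrid
from afmstate.state_space import fit_state_model

DESK_SEED = 7

#: Desk-scale model/training configuration used across the suite.
DESK_MODEL = dict(image_px=36, patch_px=6, enc_layers=4, enc_dim=128,
                  dec_layers=2, dec_dim=64, heads=8, cls_layers=2)
#: The reference batch/lr (192 / 2e-3) gives too few optimisation steps at
#: this data scale; the desk recipe trades batch size for steps (see
#: docs/methods.md, "Desk-scale configuration").
DESK_TRAIN = dict(epochs=10, batch=24, lr_max=5e-4, warmup_epochs=1,
                  seed=DESK_SEED)
DESK_N_PAIRS = 5000


@dataclass
class DeskArtifacts:
    spec: HingeSpec
    ens: object
    planted: np.ndarray
    sm: object
    train_paths: list
    val_paths: list
    net: object
    history: list
    grid: ImageGrid


@pytest.fixture(scope="session")
def hinge_world():
    """Seeded hinge ensemble with its fitted state model (fast)."""
    spec = HingeSpec(seed=DESK_SEED)
    ens, planted = make_hinge_ensemble(spec)
    sm = fit_state_model(ens, k_range=range(2, 9), seed=DESK_SEED)
    return spec, ens, planted, sm


@pytest.fixture(scope="session")
def desk_model(hinge_world, tmp_path_factory) -> DeskArtifacts:
    """Train the small autoencoder on the hinge fixture (built once)."""
    from afmstate.dataset import cache_samples, load_batches

    spec, ens, planted, sm = hinge_world
    root = tmp_path_factory.mktemp("desk")
    train_paths = build_dataset(ens, sm, DESK_N_PAIRS, root / "train",
                                seed=DESK_SEED)
    val_paths = build_dataset(ens, sm, 480, root / "val", seed=DESK_SEED + 1)
    train_cache = cache_samples(train_paths)
    val_cache = cache_samples(val_paths)

    tcfg = TrainConfig(**DESK_TRAIN)
    cfg = ModelConfig(n_states=sm.K, **DESK_MODEL)
    counter = [0]

    def train_stream():
        rng = substream(DESK_SEED, f"train.{counter[0]}")
        counter[0] += 1
        return load_batches(train_cache, tcfg.batch, rng, augment=True)

    def val_stream():
        return load_batches(val_cache, tcfg.batch, substream(DESK_SEED, "val"),
                            augment=False)

    net = build_model(cfg, seed=DESK_SEED)
    net, history = train(net, train_stream, val_stream, tcfg,
                         steps_per_epoch=int(np.ceil(DESK_N_PAIRS / tcfg.batch)))
    return DeskArtifacts(spec=spec, ens=ens, planted=planted, sm=sm,
                         train_paths=train_paths, val_paths=val_paths,
                         net=net, history=history, grid=ImageGrid.centered())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
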