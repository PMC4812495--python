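"""Pathway and multiscale training: convergence, determinism, freezing."""

import numpy as np
import pytest

from mscnnseg.errors import ConfigurationError, DegenerateInputError
from mscnnseg.network.model import build_pathway
from mscnnseg.network.train import TrainConfig, train_multiscale, train_pathway


def _separable_patches(rng, scale=12, n_per_class=60, classes=(0, 2)):
    """Disjoint constant-intensity patches: trivially separable."""
    X, y = [], []
    for i, cls in enumerate(classes):
        base = np.full((n_per_class, scale, scale, 4), float(2 * i - 1), np.float32)
        X.append(base + rng.normal(0, 0.05, base.shape).astype(np.float32))
        y.extend([cls] * n_per_class)
    return np.concatenate(X), np.array(y)


def test_separable_two_class_problem_is_learned(rng):
    X, y = _separable_patches(rng)
    cfg = TrainConfig(iterations=200, batch_size=32, seed=0)
    _, _, hist = train_pathway(X, y, 12, profile="desk", config=cfg)
    assert hist["train_accuracy"] >= 0.99


def test_zero_iterations_rejected():
    with pytest.raises(ConfigurationError):
        TrainConfig(iterations=0)


def test_single_class_training_rejected(rng):
    X = rng.standard_normal((20, 12, 12, 4)).astype(np.float32)
    y = np.full(20, 2)
    with pytest.raises(DegenerateInputError):
        train_pathway(X, y, 12, profile="desk")


def test_same_seed_gives_identical_losses_and_weights(rng):
    X, y = _separable_patches(rng)
    cfg = TrainConfig(iterations=50, batch_size=16, seed=11)
    pw1, _, h1 = train_pathway(X, y, 12, profile="desk", config=cfg)
    pw2, _, h2 = train_pathway(X, y, 12, profile="desk", config=cfg)
    assert np.array_equal(h1["loss"], h2["loss"])
    for l1, l2 in zip(pw1.layers, pw2.layers):
        assert np.array_equal(l1.weights, l2.weights)
    cfg2 = TrainConfig(iterations=50, batch_size=16, seed=12)
    _, _, h3 = train_pathway(X, y, 12, profile="desk", config=cfg2)
    assert not np.array_equal(h1["loss"], h3["loss"])


def test_loss_moving_average_non_increasing_on_separable_data(rng):
    """100-iteration moving average of the loss never increases on
    separable synthetic data."""
    X, y = _separable_patches(rng, n_per_class=100)
    cfg = TrainConfig(iterations=400, batch_size=32, seed=3)
    _, _, hist = train_pathway(X, y, 12, profile="desk", config=cfg)
    loss = hist["loss"]
    windows = [loss[i:i + 100].mean() for i in range(0, 400, 100)]
    assert all(b <= a + 1e-9 for a, b in zip(windows, windows[1:]))


def _multiscale_patchset(rng, n_per_class=40):
    scales = (48, 28, 12)
    X = {s: [] for s in scales}
    y = []
    for i, cls in enumerate((0, 2, 4)):
        for s in scales:
            base = np.full((n_per_class, s, s, 4), float(i - 1), np.float32)
            X[s].append(base + rng.normal(0, 0.05, base.shape).astype(np.float32))
        y.extend([cls] * n_per_class)
    return {s: np.concatenate(X[s]) for s in scales}, np.array(y)


@pytest.fixture(scope="module")
def trained_multiscale():
    rng = np.random.default_rng(0)
    patches, y = _multiscale_patchset(rng)
    pathways = {}
    for s in (48, 28, 12):
        cfg = TrainConfig(iterations=60, batch_size=32, seed=s)
        pw, _, _ = train_pathway(patches[s], y, s, profile="desk", config=cfg)
        pathways[s] = pw
    cfg = TrainConfig(iterations=200, batch_size=32, seed=5)
    model = train_multiscale(patches, y, pathways, head_hidden=(32, 16), config=cfg)
    return patches, y, pathways, model


def test_multiscale_head_learns_separable_problem(trained_multiscale):
    patches, y, _, model = trained_multiscale
    probs = model.forward_patches(patches)
    assert (np.argmax(probs, axis=1) == y).mean() >= 0.95


def test_frozen_pathways_unchanged_by_head_training(trained_multiscale):
    patches, y, pathways, model = trained_multiscale
    before = {s: [l.weights.copy() for l in pathways[s].layers] for s in pathways}
    cfg = TrainConfig(iterations=30, batch_size=16, seed=9)
    train_multiscale(patches, y, pathways, head_hidden=(16,), config=cfg)
    for s in pathways:
        for w0, layer in zip(before[s], pathways[s].layers):
            assert np.array_equal(w0, layer.weights)


def test_fine_tune_updates_pathway_weights(trained_multiscale):
    rng = np.random.default_rng(1)
    patches, y = _multiscale_patchset(rng, n_per_class=20)
    pathways = {}
    for s in (48, 28, 12):
        cfg = TrainConfig(iterations=20, batch_size=16, seed=s)
        pw, _, _ = train_pathway(patches[s], y, s, profile="desk", config=cfg)
        pathways[s] = pw
    before = {s: [l.weights.copy() for l in pathways[s].layers] for s in pathways}
    cfg = TrainConfig(iterations=20, batch_size=16, seed=2)
    train_multiscale(patches, y, pathways, head_hidden=(16,), config=cfg,
                     fine_tune=True, fine_tune_iterations=10)
    changed = any(not np.array_equal(w0, layer.weights)
                  for s in pathways
                  for w0, layer in zip(before[s], pathways[s].layers))
    assert changed


def test_scale_mismatch_between_samples_and_pathways_rejected(rng):
    patches, y = _multiscale_patchset(rng, n_per_class=10)
    pathways = {48: build_pathway(48, "desk", seed=0),
                28: build_pathway(28, "desk", seed=1),
                12: build_pathway(12, "desk", seed=2)}
    bad = dict(patches)
    bad[48] = patches[28]
    with pytest.raises(ConfigurationError):
        train_multiscale(bad, y, pathways, head_hidden=(16,),
                         config=TrainConfig(iterations=1))


def test_fused_dim_is_5504_for_reference_architecture(trained_multiscale):
    pathways = {s: build_pathway(s, "reference") for s in (48, 28, 12)}
    assert sum(p.n_features for p in pathways.values()) == 5504
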