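"""Training: separate per-pathway learning, then the fused multiscale head.

Pathway weights are learnt separately, each pathway with a temporary fully
connected classifier of its own; the three trained streams are then combined
and a three-layer head is trained on the standardized fused features.  The
optimizer is plain mini-batch SGD (momentum optional, off by default) on the
multinomial cross-entropy; an "iteration" is one mini-batch update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from ..errors import ConfigurationError, DegenerateInputError
from . import ops
from .model import (N_CLASSES, Head, MultiscaleModel, Pathway, PROFILES,
                    build_pathway)

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimizer settings.  The reference configuration is batch 128,
    learning rate 0.01; iterations default to 1000 mini-batch updates."""

    iterations: int = 1000
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


class _SGD:
    """Velocity store for SGD with momentum (one slot per parameter tensor)."""

    def __init__(self, lr: float, momentum: float):
        self.lr = lr
        self.momentum = momentum
        self._vel: Dict[tuple, np.ndarray] = {}


def _as_network_input(patches: np.ndarray) -> np.ndarray:
    """(n, s, s, 4) patch layout -> (n, 4, s, s) network layout."""
    return np.ascontiguousarray(patches.transpose(0, 3, 1, 2)).astype(np.float32)


def _check_labels(y: np.ndarray):
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateInputError("training set contains a single class")
    return classes


def train_pathway(X: np.ndarray, y: np.ndarray, scale: int,
                  profile: str = "desk",
                  layers: Optional[Sequence[Tuple[int, int]]] = None,
                  pool: Optional[Tuple[int, int]] = None,
                  head_hidden: Optional[Sequence[int]] = None,
                  config: Optional[TrainConfig] = None):
    """Train one pathway with an attached temporary classifier head.

    ``X`` is (n, scale, scale, 4) patches, ``y`` their center labels.  Returns
    ``(pathway, head, history)`` where history holds the per-iteration loss
    and the final training accuracy.  Reproducible under ``config.seed``.
    """
    config = config or TrainConfig()
    _check_labels(y)
    if X.shape[1] != scale or X.shape[2] != scale:
        raise ConfigurationError(f"patches of shape {X.shape[1:3]} do not match scale {scale}")
    rng = np.random.default_rng(config.seed)
    if layers is None:
        pathway = build_pathway(scale, profile=profile)
    else:
        pathway = build_pathway(scale, layers=layers, pool=pool)
    pathway.init_weights(rng)
    if head_hidden is None:
        head_hidden = PROFILES.get(profile, PROFILES["desk"])["head_hidden"]
    head = Head((pathway.n_features, *head_hidden, N_CLASSES)).init_weights(rng)

    Xn = _as_network_input(X)
    yi = np.asarray(y, dtype=np.int64)
    opt = _SGD(config.learning_rate, config.momentum)
    losses = np.empty(config.iterations, dtype=np.float64)
    for it in range(config.iterations):
        idx = rng.integers(0, len(Xn), size=min(config.batch_size, len(Xn)))
        xb, yb = Xn[idx], yi[idx]
        feats, pcache = pathway.forward(xb, want_cache=True)
        flat = feats.reshape(len(xb), -1)
        logits, hcache = head.forward(flat, want_cache=True)
        loss, dlogits = ops.softmax_cross_entropy(logits, yb)
        losses[it] = loss
        hgrads, dflat = head.backward(hcache, dlogits)
        pgrads, _ = pathway.backward(pcache, dflat.reshape(feats.shape))
        _apply_head(opt, head, hgrads)
        _apply_pathway(opt, pathway, pgrads)

    acc = _training_accuracy(pathway, head, Xn, yi)
    history = {"loss": losses, "train_accuracy": acc}
    return pathway, head, history


def _apply_head(opt: _SGD, head: Head, grads):
    for i, (dw, db) in enumerate(grads):
        v = opt._vel.get(("head_w", id(head), i))
        vw = opt.momentum * (v if v is not None else 0.0) - opt.lr * dw
        opt._vel[("head_w", id(head), i)] = vw
        head.weights[i] = (head.weights[i] + vw).astype(np.float32)
        v = opt._vel.get(("head_b", id(head), i))
        vb = opt.momentum * (v if v is not None else 0.0) - opt.lr * db
        opt._vel[("head_b", id(head), i)] = vb
        head.biases[i] = (head.biases[i] + vb).astype(np.float32)


def _apply_pathway(opt: _SGD, pathway: Pathway, grads):
    for i, (dw, db) in enumerate(grads):
        layer = pathway.layers[i]
        v = opt._vel.get(("pw_w", id(layer)))
        vw = opt.momentum * (v if v is not None else 0.0) - opt.lr * dw
        opt._vel[("pw_w", id(layer))] = vw
        layer.weights = (layer.weights + vw).astype(np.float32)
        v = opt._vel.get(("pw_b", id(layer)))
        vb = opt.momentum * (v if v is not None else 0.0) - opt.lr * db
        opt._vel[("pw_b", id(layer))] = vb
        layer.bias = (layer.bias + vb).astype(np.float32)


def _training_accuracy(pathway: Pathway, head: Head, Xn, yi, chunk: int = 512) -> float:
    correct = 0
    for i in range(0, len(Xn), chunk):
        feats = pathway.forward(Xn[i:i + chunk])
        logits = head.forward(feats.reshape(feats.shape[0], -1))
        correct += int((np.argmax(logits, axis=1) == yi[i:i + chunk]).sum())
    return correct / len(Xn)


def pathway_features(pathway: Pathway, X: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Flattened pathway outputs for (n, s, s, 4) patches, in chunks."""
    Xn = _as_network_input(X)
    out = []
    for i in range(0, len(Xn), chunk):
        f = pathway.forward(Xn[i:i + chunk])
        out.append(f.reshape(f.shape[0], -1))
    return np.concatenate(out, axis=0)


def train_multiscale(patches_by_scale: Dict[int, np.ndarray], y: np.ndarray,
                     pathways: Dict[int, Pathway],
                     head_hidden: Sequence[int] = (256, 64),
                     config: Optional[TrainConfig] = None,
                     fine_tune: bool = False,
                     fine_tune_iterations: Optional[int] = None) -> MultiscaleModel:
    """Train the fused-feature head on top of pre-trained pathways.

    Pathway weights stay frozen by default; with ``fine_tune=True`` the whole
    network is jointly refined afterwards.  Fused features are standardized
    (training-set mean/sd, stored on the model).
    """
    config = config or TrainConfig()
    _check_labels(y)
    for s, pw in pathways.items():
        if s not in patches_by_scale:
            raise ConfigurationError(f"no patches for pathway scale {s}")
        if patches_by_scale[s].shape[1] != pw.scale:
            raise ConfigurationError(
                f"patch size {patches_by_scale[s].shape[1]} != pathway scale {pw.scale}")

    scales = sorted(pathways, reverse=True)
    feats = np.concatenate([pathway_features(pathways[s], patches_by_scale[s])
                            for s in scales], axis=1)
    mean = feats.mean(axis=0)
    sd = np.maximum(feats.std(axis=0), 1e-6).astype(np.float32)
    fz = ((feats - mean) / sd).astype(np.float32)

    rng = np.random.default_rng(config.seed)
    head = Head((fz.shape[1], *head_hidden, N_CLASSES)).init_weights(rng)
    yi = np.asarray(y, dtype=np.int64)
    opt = _SGD(config.learning_rate, config.momentum)
    for it in range(config.iterations):
        idx = rng.integers(0, len(fz), size=min(config.batch_size, len(fz)))
        logits, hcache = head.forward(fz[idx], want_cache=True)
        loss, dlogits = ops.softmax_cross_entropy(logits, yi[idx])
        hgrads, _ = head.backward(hcache, dlogits)
        _apply_head(opt, head, hgrads)

    model = MultiscaleModel({s: pathways[s] for s in scales}, head,
                            feature_mean=mean.astype(np.float32), feature_sd=sd,
                            provenance={"fine_tuned": bool(fine_tune)})

    if fine_tune:
        _joint_fine_tune(model, patches_by_scale, yi, config,
                         fine_tune_iterations or config.iterations, rng)
    return model


def _joint_fine_tune(model: MultiscaleModel, patches_by_scale, yi,
                     config: TrainConfig, iterations: int,
                     rng: np.random.Generator):
    """Joint refinement of pathways + head through the fused features.

    Runs at a tenth of the head learning rate (the usual practice when
    unfreezing a pre-trained trunk); gradients through feature dimensions
    whose training-set sd hit the numerical floor are zeroed, since those
    dimensions carry no signal and 1/sd would explode.
    """
    Xn = {s: _as_network_input(patches_by_scale[s]) for s in model.scales}
    n = len(yi)
    opt = _SGD(config.learning_rate * 0.1, config.momentum)
    inv_sd = np.where(model.feature_sd > 1e-5,
                      1.0 / model.feature_sd, 0.0).astype(np.float32)
    splits = np.cumsum([model.pathways[s].n_features for s in model.scales])[:-1]
    for it in range(iterations):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        feats, caches = {}, {}
        for s, pw in model.pathways.items():
            f, c = pw.forward(Xn[s][idx], want_cache=True)
            feats[s], caches[s] = f, c
        fused = model.standardize(model.fuse(feats)).astype(np.float32)
        logits, hcache = model.head.forward(fused, want_cache=True)
        loss, dlogits = ops.softmax_cross_entropy(logits, yi[idx])
        hgrads, dfused = model.head.backward(hcache, dlogits)
        dfused = dfused * inv_sd  # undo standardization scaling
        parts = np.split(dfused, splits, axis=1)
        _apply_head(opt, model.head, hgrads)
        for s, part in zip(model.scales, parts):
            pgrads, _ = model.pathways[s].backward(caches[s], part.reshape(feats[s].shape))
            _apply_pathway(opt, model.pathways[s], pgrads)
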