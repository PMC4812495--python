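"""scikit-learn style estimators wrapping the patch CNNs.

``PatchCNNClassifier`` is one single-scale pathway with its own classifier
head; ``MultiscaleCNNClassifier`` trains the three pathways separately and
then a fused-feature head.  Both follow the sklearn contract (get_params /
set_params, fitted attributes with trailing underscores, ``fit`` returning
``self``) so they compose with sklearn model selection; ``ScaleSelector``
is a fit-only meta-estimator for the prior patch-size selection.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError
from .network import train as _train
from .network.model import N_CLASSES, PROFILES, MultiscaleModel
from .scale_selection import ProxyConfig, run_prior_selection


def _patch_matrix(X, scale: int) -> np.ndarray:
    """Accept (n, s, s, 4) patches or their (n, s*s*4) flattening."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X.reshape(len(X), scale, scale, 4)
    if X.ndim != 4 or X.shape[1] != scale or X.shape[2] != scale or X.shape[3] != 4:
        raise ValueError(f"expected (n, {scale}, {scale}, 4) patches, got {X.shape}")
    return X


class PatchCNNClassifier(ClassifierMixin, BaseEstimator):
    """Single-pathway patch CNN (one scale) with a temporary classifier head.

    Parameters mirror the reference training configuration: ``iterations``
    counts mini-batch SGD updates (default 1000), ``profile`` picks the map
    widths ("reference" or the CPU-friendly "desk").
    """

    def __init__(self, scale: int = 28, profile: str = "desk",
                 layers: Optional[Sequence[Tuple[int, int]]] = None,
                 pool: Optional[Tuple[int, int]] = None,
                 head_hidden: Optional[Sequence[int]] = None,
                 iterations: int = 1000, batch_size: Optional[int] = None,
                 learning_rate: float = 0.01, momentum: float = 0.0,
                 seed: int = 0):
        self.scale = scale
        self.profile = profile
        self.layers = layers
        self.pool = pool
        self.head_hidden = head_hidden
        self.iterations = iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.seed = seed

    def _config(self) -> _train.TrainConfig:
        batch = self.batch_size
        if batch is None:
            batch = PROFILES.get(self.profile, PROFILES["desk"])["batch_size"]
        return _train.TrainConfig(iterations=self.iterations, batch_size=batch,
                                  learning_rate=self.learning_rate,
                                  momentum=self.momentum, seed=self.seed)

    def fit(self, X, y):
        X = _patch_matrix(X, self.scale)
        y = np.asarray(y, dtype=np.int64)
        self.pathway_, self.head_, history = _train.train_pathway(
            X, y, self.scale, profile=self.profile, layers=self.layers,
            pool=self.pool, head_hidden=self.head_hidden, config=self._config())
        self.classes_ = np.arange(N_CLASSES)
        self.loss_curve_ = history["loss"]
        self.train_accuracy_ = history["train_accuracy"]
        self.n_features_in_ = self.scale * self.scale * 4
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = _patch_matrix(X, self.scale)
        from .network import ops
        feats = _train.pathway_features(self.pathway_, X)
        logits = self.head_.forward(feats)
        return ops.softmax(logits)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def as_model(self) -> MultiscaleModel:
        """Wrap the fitted pathway + head as a one-pathway model, so the
        segmenter can run single-scale sliding-window inference."""
        return MultiscaleModel({self.scale: self.pathway_}, self.head_)


class MultiscaleCNNClassifier(ClassifierMixin, BaseEstimator):
    """Three-pathway multiscale patch CNN with a fused-feature head.

    ``fit`` accepts either a dict mapping scale -> (n, s, s, 4) patch arrays
    (co-centered stacks) or a single 2D array whose columns are the flattened
    patches concatenated in descending scale order.  Pathways are trained
    separately, then frozen while the head learns on the standardized fused
    features (set ``fine_tune=True`` for joint refinement).
    """

    def __init__(self, scales: Tuple[int, ...] = (48, 28, 12), profile: str = "desk",
                 pathway_iterations: int = 1000, head_iterations: int = 1000,
                 batch_size: Optional[int] = None, learning_rate: float = 0.01,
                 momentum: float = 0.0, fine_tune: bool = False,
                 fine_tune_iterations: Optional[int] = None, seed: int = 0):
        self.scales = scales
        self.profile = profile
        self.pathway_iterations = pathway_iterations
        self.head_iterations = head_iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.fine_tune = fine_tune
        self.fine_tune_iterations = fine_tune_iterations
        self.seed = seed

    def _split(self, X) -> Dict[int, np.ndarray]:
        if isinstance(X, dict):
            return {int(s): _patch_matrix(X[s], int(s)) for s in X}
        X = np.asarray(X, dtype=np.float32)
        widths = [s * s * 4 for s in sorted(self.scales, reverse=True)]
        if X.ndim != 2 or X.shape[1] != sum(widths):
            raise ValueError(
                f"expected dict of patch stacks or (n, {sum(widths)}) matrix, got {X.shape}")
        out, start = {}, 0
        for s, w in zip(sorted(self.scales, reverse=True), widths):
            out[s] = X[:, start:start + w].reshape(len(X), s, s, 4)
            start += w
        return out

    def fit(self, X, y):
        patches = self._split(X)
        missing = [s for s in self.scales if s not in patches]
        if missing:
            raise ConfigurationError(f"missing patch stacks for scales {missing}")
        y = np.asarray(y, dtype=np.int64)
        batch = self.batch_size or PROFILES.get(self.profile, PROFILES["desk"])["batch_size"]
        seeds = np.random.SeedSequence(self.seed).generate_state(len(self.scales) + 1) % (2 ** 31)

        self.pathways_ = {}
        self.pathway_train_accuracy_ = {}
        for i, s in enumerate(sorted(self.scales, reverse=True)):
            cfg = _train.TrainConfig(iterations=self.pathway_iterations, batch_size=batch,
                                     learning_rate=self.learning_rate,
                                     momentum=self.momentum, seed=int(seeds[i]))
            pw, _, hist = _train.train_pathway(patches[s], y, s, profile=self.profile,
                                               config=cfg)
            self.pathways_[s] = pw
            self.pathway_train_accuracy_[s] = hist["train_accuracy"]

        head_hidden = PROFILES.get(self.profile, PROFILES["desk"])["head_hidden"]
        cfg = _train.TrainConfig(iterations=self.head_iterations, batch_size=batch,
                                 learning_rate=self.learning_rate,
                                 momentum=self.momentum, seed=int(seeds[-1]))
        self.model_ = _train.train_multiscale(
            patches, y, self.pathways_, head_hidden=head_hidden, config=cfg,
            fine_tune=self.fine_tune, fine_tune_iterations=self.fine_tune_iterations)
        self.fused_dim_ = self.model_.fused_dim
        self.classes_ = np.arange(N_CLASSES)
        self.n_features_in_ = sum(s * s * 4 for s in self.scales)
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.forward_patches(self._split(X))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class ScaleSelector(BaseEstimator):
    """Prior patch-size selection as a fit-only estimator.

    ``fit(cases)`` ranks ``candidates`` by proxy accuracy on a random
    ``fraction`` of the training slices; fitted attributes expose the ranking.
    """

    def __init__(self, candidates: Tuple[int, ...] = (12, 20, 28, 36, 48),
                 fraction: float = 0.01, proxy: Optional[ProxyConfig] = None,
                 seed: int = 0):
        self.candidates = candidates
        self.fraction = fraction
        self.proxy = proxy
        self.seed = seed

    def fit(self, cases, y=None):
        self.ranking_ = run_prior_selection(cases, self.candidates,
                                            fraction=self.fraction,
                                            proxy=self.proxy, seed=self.seed)
        self.top3_ = self.ranking_.top3
        self.accuracies_ = dict(self.ranking_.accuracies)
        return self
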