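"""Automatic selection of proper patch sizes before training.

A cheap prior procedure: draw a small random fraction of the training 2D
slices (1% by default), and for every candidate patch size train a shallow
single-pathway proxy network on class-balanced patches from those slices.
Candidates are ranked by held-out patch classification accuracy and the
top three become the pathway scales of the multiscale model.

Each candidate gets an independent sub-seed derived from (master seed, scale),
so adding or removing other candidates never changes an existing candidate's
draws or its ranking relative to the rest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .network.train import TrainConfig, train_pathway
from .patches import sample_patches_from_slices, sample_slice_fraction

logger = logging.getLogger(__name__)


@dataclass
class ProxyConfig:
    """Shallow, cheap proxy network used only for ranking candidate scales."""

    kernel: int = 3
    conv_maps: Tuple[int, int] = (8, 8)
    head_hidden: Tuple[int, ...] = (32,)
    iterations: int = 200
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.0
    per_class_quota: int = 200
    holdout_fraction: float = 0.2


@dataclass
class ScaleRanking:
    """Per-candidate proxy accuracies and the selected top-3 scale set."""

    candidates: Tuple[int, ...]
    accuracies: Dict[int, float]
    top3: Tuple[int, ...]
    sample_fraction: float
    seed: int
    infeasible: Tuple[int, ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        d["accuracies"] = {str(k): v for k, v in self.accuracies.items()}
        return json.dumps(d, indent=2)


def _sub_seed(master: int, scale: int) -> int:
    """Deterministic per-candidate seed, independent of the candidate set."""
    return int(np.random.SeedSequence(entropy=(int(master), int(scale))
                                      ).generate_state(1)[0] % (2 ** 31))


def _proxy_layers(scale: int, proxy: ProxyConfig):
    """Two small conv layers, plus a 2x2 pool when the final map divides."""
    k = proxy.kernel
    side = scale - 2 * (k - 1)
    if side < 1:
        raise ConfigurationError(f"scale {scale} too small for the proxy network")
    layers = [(k, proxy.conv_maps[0]), (k, proxy.conv_maps[1])]
    pool = (2, 2) if side % 2 == 0 and side >= 2 else None
    return layers, pool


def evaluate_candidate(slices, scale: int, proxy: ProxyConfig, seed: int) -> float:
    """Held-out patch accuracy of the proxy network at one candidate scale."""
    rng = np.random.default_rng(seed)
    pset = sample_patches_from_slices(
        slices, {c: proxy.per_class_quota for c in range(5)}, (scale,), rng)
    n = len(pset)
    if n == 0:
        raise DegenerateInputError("no patches could be sampled")
    perm = rng.permutation(n)
    n_hold = max(1, int(round(proxy.holdout_fraction * n)))
    hold, train = perm[:n_hold], perm[n_hold:]
    X = pset.scale_array(scale)
    y = pset.labels
    layers, pool = _proxy_layers(scale, proxy)
    cfg = TrainConfig(iterations=proxy.iterations, batch_size=proxy.batch_size,
                      learning_rate=proxy.learning_rate, momentum=proxy.momentum,
                      seed=seed)
    pathway, head, _ = train_pathway(X[train], y[train], scale,
                                     layers=layers, pool=pool,
                                     head_hidden=proxy.head_hidden, config=cfg)
    from .network.train import _as_network_input
    feats = pathway.forward(_as_network_input(X[hold]))
    pred = np.argmax(head.forward(feats.reshape(len(hold), -1)), axis=1)
    return float((pred == y[hold]).mean())


def run_prior_selection(cases: Sequence, candidates: Sequence[int],
                        fraction: float = 0.01,
                        proxy: Optional[ProxyConfig] = None,
                        seed: int = 0) -> ScaleRanking:
    """Rank candidate patch sizes and return the top three.

    ``cases`` is a sequence of (MultimodalVolume, LabelVolume).  Candidates
    larger than the slice side (or too small for the proxy) are marked
    infeasible and excluded with a warning.  Ties rank the larger scale first
    (global context is the scarcer signal).  Fully reproducible under
    ``seed``.
    """
    candidates = tuple(int(c) for c in candidates)
    if len(candidates) < 2:
        raise ConfigurationError("need at least two candidate scales")
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("fraction must be in (0, 1]")
    proxy = proxy or ProxyConfig()

    slices = sample_slice_fraction(cases, fraction, seed=seed)
    min_side = min(min(s.shape[0], s.shape[1]) for s, _ in slices)

    accuracies: Dict[int, float] = {}
    infeasible = []
    for scale in candidates:
        if scale > min_side or scale < 2 * (proxy.kernel - 1) + 1:
            logger.warning("candidate scale %d infeasible for slice side %d; excluded",
                           scale, min_side)
            infeasible.append(scale)
            continue
        accuracies[scale] = evaluate_candidate(slices, scale, proxy,
                                               _sub_seed(seed, scale))
        logger.info("candidate scale %d: held-out accuracy %.3f", scale, accuracies[scale])

    if not accuracies:
        raise ConfigurationError("no feasible candidate scales")
    ranked = sorted(accuracies, key=lambda s: (-accuracies[s], -s))
    top3 = tuple(ranked[:3])
    if len(top3) < 3:
        logger.warning("only %d feasible candidate(s); top3 degenerates to %s",
                       len(top3), top3)
    return ScaleRanking(candidates=candidates, accuracies=accuracies, top3=top3,
                        sample_fraction=fraction, seed=seed,
                        infeasible=tuple(infeasible))
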