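"""Architecture of the single-pathway CNNs and the fused three-pathway model.

The reference architecture classifies the center pixel of
co-centered 48/28/12 multimodal patches:

* 48-pathway: five conv layers with kernels 11, 11, 11, 11, 5 (C1 produces 12
  maps of 38x38), then a (1, 4) max pool turning the 1024 final 4x4 maps into
  4x1 maps;
* 28-pathway: kernels 11, 11, 5 ending in 72 maps of 4x4;
* 12-pathway: kernels 5, 5 ending in 16 maps of 4x4.

Flattening and concatenating the three outputs gives the 5504-long fused
vector (1024*4 + 72*16 + 16*16) consumed by a three-layer fully connected
classifier over the five tissue classes.  A thin "desk" profile keeps the
same scales, kernels and layer counts but shrinks map counts so the whole
pipeline trains in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..errors import ConfigurationError, ShapeError
from . import ops

N_CLASSES = 5
IN_CHANNELS = 4


@dataclass
class ConvLayerSpec:
    """One convolutional layer: kernel size, output map count, parameters."""

    kernel_size: Tuple[int, int]
    out_maps: int
    weights: Optional[np.ndarray] = None  # (S, C, kh, kw)
    bias: Optional[np.ndarray] = None     # (S,)

    def __post_init__(self):
        kh, kw = self.kernel_size
        if kh < 1 or kw < 1 or self.out_maps < 1:
            raise ConfigurationError("kernel dims and out_maps must be >= 1")
        if self.weights is not None:
            if self.weights.shape[0] != self.out_maps or self.weights.shape[2:] != (kh, kw):
                raise ShapeError(f"weight tensor {self.weights.shape} inconsistent with spec")


#: architecture profiles: same scales/kernels, different map widths
PROFILES = {
    "reference": {
        "pathways": {
            48: {"layers": [(11, 12), (11, 32), (11, 96), (11, 256), (5, 1024)],
                 "pool": (1, 4), "declared_output": (1024, (4, 1))},
            28: {"layers": [(11, 12), (11, 32), (5, 72)],
                 "pool": None, "declared_output": (72, (4, 4))},
            12: {"layers": [(5, 12), (5, 16)],
                 "pool": None, "declared_output": (16, (4, 4))},
        },
        "head_hidden": (256, 64),
        "batch_size": 128,
    },
    "desk": {
        "pathways": {
            48: {"layers": [(11, 4), (11, 4), (11, 6), (11, 8), (5, 16)],
                 "pool": (1, 4), "declared_output": (16, (4, 1))},
            28: {"layers": [(11, 4), (11, 6), (5, 16)],
                 "pool": None, "declared_output": (16, (4, 4))},
            12: {"layers": [(5, 6), (5, 8)],
                 "pool": None, "declared_output": (8, (4, 4))},
        },
        "head_hidden": (48, 24),
        "batch_size": 32,
    },
}


def symbolic_output(scale: int, layers: Sequence[Tuple[int, int]],
                    pool: Optional[Tuple[int, int]]):
    """Propagate the valid-conv shape law through a layer stack.

    Returns (map count, (h, w)) after the optional pool.  Raises
    :class:`ShapeError` when a kernel outgrows its input or the pool window
    does not divide the final map.
    """
    h = w = scale
    maps = IN_CHANNELS
    for k, s in layers:
        kh, kw = (k, k) if np.isscalar(k) else k
        h = ops.conv_out_side(h, kh)
        w = ops.conv_out_side(w, kw)
        maps = s
    if pool is not None:
        ph, pw = pool
        if h % ph or w % pw:
            raise ShapeError(f"pool window {pool} does not divide map {(h, w)}")
        h, w = h // ph, w // pw
    return maps, (h, w)


class Pathway:
    """One single-scale convolutional stream (conv stack + optional max pool)."""

    def __init__(self, scale: int, layers: List[ConvLayerSpec],
                 pool: Optional[Tuple[int, int]] = None,
                 declared_output: Optional[Tuple[int, Tuple[int, int]]] = None):
        self.scale = int(scale)
        self.layers = layers
        self.pool = tuple(pool) if pool is not None else None
        shape = symbolic_output(scale, [(l.kernel_size, l.out_maps) for l in layers], self.pool)
        if declared_output is not None:
            declared = (declared_output[0], tuple(declared_output[1]))
            if (shape[0], tuple(shape[1])) != declared:
                raise ConfigurationError(
                    f"composed output {shape} disagrees with declared output {declared}")
        self.output_shape = (shape[0], tuple(shape[1]))

    @property
    def n_features(self) -> int:
        maps, (h, w) = self.output_shape
        return maps * h * w

    def init_weights(self, rng: np.random.Generator):
        c = IN_CHANNELS
        for layer in self.layers:
            kh, kw = layer.kernel_size
            fan_in = c * kh * kw
            layer.weights = ops.he_normal(rng, (layer.out_maps, c, kh, kw), fan_in)
            layer.bias = np.zeros(layer.out_maps, dtype=np.float32)
            c = layer.out_maps
        return self

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x is (N, 4, scale, scale); returns pooled feature maps (N, S, h, w)."""
        cache = []
        a = x
        for layer in self.layers:
            z = ops.conv2d(a, layer.weights, layer.bias)
            if want_cache:
                cache.append((a, z))
            a = ops.relu(z)
        pre_pool = a
        if self.pool is not None:
            a = ops.max_pool(a, self.pool)
        if want_cache:
            return a, (cache, pre_pool)
        return a

    def backward(self, cache, dfeat: np.ndarray):
        """Gradients for every layer given d(pooled output); returns list of
        (dW, db) aligned with ``self.layers`` plus d(input)."""
        conv_cache, pre_pool = cache
        da = dfeat
        if self.pool is not None:
            da = ops.max_pool_backward(pre_pool, self.pool, da)
        grads: List[Tuple[np.ndarray, np.ndarray]] = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, -1, -1):
            a_in, z = conv_cache[i]
            dz = ops.relu_backward(z, da)
            dw, db, dx = ops.conv2d_backward(a_in, self.layers[i].weights, dz)
            grads[i] = (dw, db)
            da = dx
        return grads, da

    def parameters(self):
        for layer in self.layers:
            yield layer, "weights"
            yield layer, "bias"


class Head:
    """Fully connected classifier: hidden ReLU layers, softmax output."""

    def __init__(self, sizes: Sequence[int]):
        # sizes = (in, hidden..., out)
        self.sizes = tuple(int(s) for s in sizes)
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []

    def init_weights(self, rng: np.random.Generator):
        self.weights, self.biases = [], []
        for din, dout in zip(self.sizes[:-1], self.sizes[1:]):
            self.weights.append(ops.he_normal(rng, (din, dout), din))
            self.biases.append(np.zeros(dout, dtype=np.float32))
        return self

    def forward(self, x: np.ndarray, want_cache: bool = False):
        cache = []
        a = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = ops.dense(a, w, b)
            if want_cache:
                cache.append((a, z))
            a = ops.relu(z) if i < last else z
        if want_cache:
            return a, cache
        return a

    def backward(self, cache, dlogits: np.ndarray):
        grads: List[Tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)
        da = dlogits
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            a_in, z = cache[i]
            dz = da if i == last else ops.relu_backward(z, da)
            dw, db, dx = ops.dense_backward(a_in, self.weights[i], dz)
            grads[i] = (dw, db)
            da = dx
        return grads, da

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return ops.softmax(self.forward(x))


class MultiscaleModel:
    """Trained pathways plus the fused-feature classifier head.

    Fused features are standardized with per-dimension mean/sd estimated on
    the training set (stored on the model) before entering the head.
    """

    def __init__(self, pathways: Dict[int, Pathway], head: Head,
                 feature_mean: Optional[np.ndarray] = None,
                 feature_sd: Optional[np.ndarray] = None,
                 provenance: Optional[dict] = None):
        self.pathways = {int(s): p for s, p in sorted(pathways.items(), reverse=True)}
        self.head = head
        fused = sum(p.n_features for p in self.pathways.values())
        if head.sizes[0] != fused:
            raise ConfigurationError(f"head input {head.sizes[0]} != fused dim {fused}")
        if head.sizes[-1] != N_CLASSES:
            raise ConfigurationError(f"head must end in {N_CLASSES} classes")
        self.feature_mean = feature_mean if feature_mean is not None else np.zeros(fused, np.float32)
        self.feature_sd = feature_sd if feature_sd is not None else np.ones(fused, np.float32)
        self.provenance = provenance or {}

    @property
    def scales(self) -> Tuple[int, ...]:
        return tuple(self.pathways)

    @property
    def fused_dim(self) -> int:
        return sum(p.n_features for p in self.pathways.values())

    def fuse(self, pathway_feats: Dict[int, np.ndarray]) -> np.ndarray:
        """Flatten per-pathway maps and concatenate in descending scale order."""
        missing = [s for s in self.pathways if s not in pathway_feats]
        if missing:
            raise ValueError(f"missing pathway outputs for scales {missing}")
        n = next(iter(pathway_feats.values())).shape[0]
        return np.concatenate(
            [pathway_feats[s].reshape(n, -1) for s in self.pathways], axis=1)

    def standardize(self, fused: np.ndarray) -> np.ndarray:
        return (fused - self.feature_mean) / self.feature_sd

    def forward_patches(self, patches_by_scale: Dict[int, np.ndarray]) -> np.ndarray:
        """(n, s, s, 4) patch arrays per scale -> (n, 5) class probabilities."""
        feats = {}
        for s, pw in self.pathways.items():
            x = np.ascontiguousarray(patches_by_scale[s].transpose(0, 3, 1, 2)).astype(np.float32)
            feats[s] = pw.forward(x)
        fused = self.standardize(self.fuse(feats))
        return self.head.predict_proba(fused)


# ---------------------------------------------------------------------------
# construction and functional wrappers
# ---------------------------------------------------------------------------

def build_pathway(scale: int, profile: str = "reference",
                  layers: Optional[Sequence[Tuple[int, int]]] = None,
                  pool: Optional[Tuple[int, int]] = None,
                  declared_output=None, seed: Optional[int] = None) -> Pathway:
    """Construct (and optionally initialize) a single-scale pathway.

    Supported scales with a profile are 48, 28 and 12; any other scale
    requires an explicit ``layers`` list of (kernel, out_maps) pairs.
    Construction fails loudly if the composed shape chain disagrees with the
    declared output.
    """
    if layers is None:
        prof = PROFILES.get(profile)
        if prof is None:
            raise ConfigurationError(f"unknown profile: {profile}")
        cfg = prof["pathways"].get(int(scale))
        if cfg is None:
            raise ConfigurationError(
                f"scale {scale} not in profile {profile!r}; pass an explicit layer list")
        layers, pool = cfg["layers"], cfg["pool"]
        if declared_output is None:
            declared_output = cfg["declared_output"]
    specs = [ConvLayerSpec((k, k), m) for k, m in layers]
    pw = Pathway(scale, specs, pool=pool, declared_output=declared_output)
    if seed is not None:
        pw.init_weights(np.random.default_rng(seed))
    return pw


def conv_forward(inputs: np.ndarray, layer: ConvLayerSpec, activation: str = "relu") -> np.ndarray:
    """Single-sample convolutional layer: (H, W, C) or (C, H, W) in,
    (S, oh, ow) feature maps out."""
    x = np.asarray(inputs, dtype=np.float32)
    if x.ndim != 3:
        raise ShapeError("expected a multi-channel 2D array")
    c = layer.weights.shape[1]
    if x.shape[-1] == c and x.shape[0] != c:
        x = x.transpose(2, 0, 1)
    out = ops.conv2d(x[None], layer.weights, layer.bias)[0]
    if activation == "relu":
        out = ops.relu(out)
    elif activation != "linear":
        raise ValueError(f"unknown activation: {activation}")
    return out


def fuse_features(pathway_outputs: Dict[int, np.ndarray]) -> np.ndarray:
    """Flatten each pathway's maps and concatenate, largest scale first."""
    if not pathway_outputs:
        raise ValueError("no pathway outputs to fuse")
    parts = [np.asarray(pathway_outputs[s]).ravel()
             for s in sorted(pathway_outputs, reverse=True)]
    return np.concatenate(parts)


def classify_head(fused: np.ndarray, head: Head) -> np.ndarray:
    """Probability simplex over the 5 tissue classes for one fused vector."""
    fused = np.asarray(fused, dtype=np.float32).reshape(1, -1)
    if fused.shape[1] != head.sizes[0]:
        raise ShapeError(f"fused length {fused.shape[1]} != head input {head.sizes[0]}")
    return head.predict_proba(fused)[0]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model: MultiscaleModel, path):
    """Single-file checkpoint (.npz): architecture JSON + per-layer tensors."""
    arch = {
        "scales": list(model.scales),
        "pathways": {
            str(s): {
                "layers": [[*p.layers[i].kernel_size, p.layers[i].out_maps]
                           for i in range(len(p.layers))],
                "pool": list(p.pool) if p.pool else None,
            } for s, p in model.pathways.items()
        },
        "head_sizes": list(model.head.sizes),
        "provenance": model.provenance,
    }
    arrays = {"feature_mean": model.feature_mean, "feature_sd": model.feature_sd}
    for s, p in model.pathways.items():
        for i, layer in enumerate(p.layers):
            arrays[f"p{s}_l{i}_w"] = layer.weights
            arrays[f"p{s}_l{i}_b"] = layer.bias
    for i, (w, b) in enumerate(zip(model.head.weights, model.head.biases)):
        arrays[f"head_l{i}_w"] = w
        arrays[f"head_l{i}_b"] = b
    np.savez(path, arch=np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> MultiscaleModel:
    with np.load(path) as data:
        arch = json.loads(bytes(data["arch"]).decode())
        pathways = {}
        for s in arch["scales"]:
            cfg = arch["pathways"][str(s)]
            specs = [ConvLayerSpec((kh, kw), m) for kh, kw, m in cfg["layers"]]
            pw = Pathway(s, specs, pool=tuple(cfg["pool"]) if cfg["pool"] else None)
            for i, layer in enumerate(pw.layers):
                layer.weights = data[f"p{s}_l{i}_w"]
                layer.bias = data[f"p{s}_l{i}_b"]
            pathways[s] = pw
        head = Head(arch["head_sizes"])
        i = 0
        while f"head_l{i}_w" in data:
            head.weights.append(data[f"head_l{i}_w"])
            head.biases.append(data[f"head_l{i}_b"])
            i += 1
        return MultiscaleModel(pathways, head,
                               feature_mean=data["feature_mean"],
                               feature_sd=data["feature_sd"],
                               provenance=arch.get("provenance", {}))
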