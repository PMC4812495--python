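"""Sliding-window segmentation with the multiscale model, and Dice evaluation.

Every pixel of every axial slice is classified from its co-centered patches
(the predicted label is the argmax of the head scores, ties going to the
lowest class index).  Because all pathway layers are stride-1 valid
convolutions followed by one non-overlapping pool, the per-pixel patch
features are computed densely: the conv stack is run once over the
(reflect-padded) slice and every pixel's final maps are read out of the
resulting planes as shifted windows, which is mathematically identical to
extracting one patch per pixel but hundreds of times faster.

Evaluation uses the Dice ratio DR(A, B) = 2|A ∩ B| / (|A| + |B|) between
predicted and reference binary masks, reported for the whole tumor (labels
1-4 merged) and per tumor class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AlignmentError
from .network import ops
from .network.model import MultiscaleModel, Pathway
from .volume_io import LabelVolume, MultimodalVolume

logger = logging.getLogger(__name__)

REGIONS = ("whole", "necrosis", "edema", "nonenhancing", "enhancing")
_REGION_LABELS = {"whole": (1, 2, 3, 4), "necrosis": (1,), "edema": (2,),
                  "nonenhancing": (3,), "enhancing": (4,)}


@dataclass
class SegmentationResult:
    predicted: LabelVolume
    probabilities: Optional[np.ndarray] = None  # (H, W, Z, 5)
    provenance: dict = field(default_factory=dict)


@dataclass
class DiceReport:
    region: str
    dice: float
    n_pred: int
    n_ref: int
    n_intersection: int


def _pad_widths(scale: int):
    before = scale // 2
    after = scale - before - 1
    return before, after


def _dense_pathway_features(pathway: Pathway, slice_chw: np.ndarray,
                            border_policy: str = "reflect") -> np.ndarray:
    """Per-pixel pathway features over a whole slice.

    ``slice_chw`` is (4, H, W).  Returns (H, W, n_features) under reflect
    padding; under "skip" only the interior where the window fits is computed
    and border pixels carry NaN.
    """
    c, h, w = slice_chw.shape
    s = pathway.scale
    before, after = _pad_widths(s)
    maps, (oh, ow) = pathway.output_shape
    m = oh * (pathway.pool[0] if pathway.pool else 1), ow * (pathway.pool[1] if pathway.pool else 1)
    mh, mw = m

    if border_policy == "reflect":
        if before >= h or before >= w:
            raise AlignmentError(
                f"slice {h}x{w} too small to reflect-pad for scale {s}")
        x = np.pad(slice_chw, ((0, 0), (before, after), (before, after)), mode="reflect")
    elif border_policy == "skip":
        x = slice_chw
    else:
        raise ValueError(f"unknown border policy: {border_policy}")

    q = x[None]
    for layer in pathway.layers:
        q = ops.relu(ops.conv2d(q, layer.weights, layer.bias))
    q = q[0]  # (maps, H', W') with H' = n_positions + mh - 1

    win = sliding_window_view(q, (mh, mw), axis=(1, 2))  # (maps, ph, pw, mh, mw)
    nph, npw = win.shape[1], win.shape[2]
    if pathway.pool is not None:
        ph, pw = pathway.pool
        win = win.reshape(maps, nph, npw, mh // ph, ph, mw // pw, pw).max(axis=(4, 6))
    feats = np.moveaxis(win, 0, 2).reshape(nph, npw, pathway.n_features)

    if border_policy == "skip":
        full = np.full((h, w, pathway.n_features), np.nan, dtype=np.float32)
        full[before:before + nph, before:before + npw] = feats
        return full
    return np.ascontiguousarray(feats, dtype=np.float32)


def segment_slice(model: MultiscaleModel, slice_stack: np.ndarray,
                  border_policy: str = "reflect", return_proba: bool = False,
                  stride: int = 1):
    """Classify every pixel of one (H, W, 4) axial slice.

    Returns the (H, W) int label map, or ``(labels, probabilities)`` with
    probabilities of shape (H, W, 5) when ``return_proba``.  Under the
    ``"skip"`` border policy the band where the largest window does not fit is
    labeled 0.  ``stride > 1`` classifies a subsampled grid and fills the rest
    by nearest neighbor.
    """
    slice_stack = np.asarray(slice_stack, dtype=np.float32)
    h, w = slice_stack.shape[:2]
    chw = np.ascontiguousarray(slice_stack.transpose(2, 0, 1))
    feats = [_dense_pathway_features(model.pathways[s], chw, border_policy)
             for s in model.scales]
    fused = np.concatenate(feats, axis=2)
    if stride > 1:
        fused = fused[::stride, ::stride]
    gh, gw = fused.shape[:2]
    fused = fused.reshape(gh * gw, -1)
    valid = ~np.isnan(fused[:, 0])
    probs = np.zeros((gh * gw, 5), dtype=np.float32)
    probs[:, 0] = 1.0
    z = model.standardize(fused[valid]).astype(np.float32)
    chunk = 8192
    out = [model.head.predict_proba(z[i:i + chunk]) for i in range(0, len(z), chunk)]
    if out:
        probs[valid] = np.concatenate(out, axis=0)
    labels = np.argmax(probs, axis=1).astype(np.int16)  # argmax: lowest index wins ties
    labels[~valid] = 0
    labels = labels.reshape(gh, gw)
    probs = probs.reshape(gh, gw, 5)
    if stride > 1:
        labels = np.repeat(np.repeat(labels, stride, axis=0), stride, axis=1)[:h, :w]
        probs = np.repeat(np.repeat(probs, stride, axis=0), stride, axis=1)[:h, :w]
    if return_proba:
        return labels, probs
    return labels


def _segment_slice_naive(model: MultiscaleModel, slice_stack: np.ndarray,
                         border_policy: str = "reflect") -> np.ndarray:
    """Reference per-pixel implementation (patch extraction + forward pass).

    Exact but slow; kept as the independent route the dense inference is
    checked against.
    """
    from .patches import extract_multiscale
    h, w = slice_stack.shape[:2]
    labels = np.zeros((h, w), dtype=np.int16)
    for r in range(h):
        for c in range(w):
            ms = extract_multiscale(slice_stack, (r, c), model.scales, border_policy)
            if ms is None:
                continue
            p = model.forward_patches({s: ms[s][None] for s in model.scales})
            labels[r, c] = int(np.argmax(p[0]))
    return labels


def segment_volume(model: MultiscaleModel, vol: MultimodalVolume,
                   border_policy: str = "reflect", keep_probabilities: bool = False,
                   stride: int = 1, z_range: Optional[Sequence[int]] = None) -> SegmentationResult:
    """Segment every axial slice independently and stack in z order.

    ``z_range`` restricts inference to a subset of slices (others are labeled
    0), which is useful for quick evaluations.
    """
    h, w, nz = vol.shape
    stack = vol.stack()
    labels = np.zeros((h, w, nz), dtype=np.int16)
    probs = np.zeros((h, w, nz, 5), dtype=np.float32) if keep_probabilities else None
    zs = range(nz) if z_range is None else z_range
    for z in zs:
        out = segment_slice(model, stack[:, :, z, :], border_policy,
                            return_proba=keep_probabilities, stride=stride)
        if keep_probabilities:
            labels[:, :, z], probs[:, :, z, :] = out
        else:
            labels[:, :, z] = out
    prov = {"border_policy": border_policy, "stride": stride}
    if border_policy == "skip":
        prov["border_band"] = "zero-filled"
    return SegmentationResult(LabelVolume(labels), probabilities=probs, provenance=prov)


def dice_ratio(a: np.ndarray, b: np.ndarray) -> float:
    """Dice ratio 2|A ∩ B| / (|A| + |B|) between two binary masks.

    Two empty masks agree perfectly on absence and score 1 (logged), so
    tumor-free slices do not poison case averages.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.debug("both masks empty; Dice defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def evaluate_case(result, reference: LabelVolume) -> Dict[str, DiceReport]:
    """Dice reports for the whole tumor and each tumor class of one case."""
    pred = result.predicted.labels if isinstance(result, SegmentationResult) else \
        (result.labels if isinstance(result, LabelVolume) else np.asarray(result))
    ref = reference.labels
    if pred.shape != ref.shape:
        raise AlignmentError(f"prediction shape {pred.shape} != reference {ref.shape}")
    reports = {}
    for region, labs in _REGION_LABELS.items():
        a = np.isin(pred, labs)
        b = np.isin(ref, labs)
        reports[region] = DiceReport(region, dice_ratio(a, b),
                                     int(a.sum()), int(b.sum()), int((a & b).sum()))
    return reports


def summarize_cases(case_reports: Sequence[Dict[str, DiceReport]]) -> Dict[str, dict]:
    """Mean and variance of Dice per region across cases."""
    out = {}
    for region in _REGION_LABELS:
        vals = np.array([r[region].dice for r in case_reports], dtype=float)
        out[region] = {"mean": float(vals.mean()), "variance": float(vals.var()),
                       "n_cases": len(vals)}
    return out


def pixel_accuracy(pred: np.ndarray, ref: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Plain per-pixel label accuracy, optionally restricted to a mask."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise AlignmentError("shape mismatch")
    if mask is not None:
        pred, ref = pred[mask], ref[mask]
    return float((pred == ref).mean())
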