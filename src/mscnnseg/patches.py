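"""Co-centered multiscale multimodal 2D patches, labeled by the center pixel.

Segmentation is phrased as patch classification: each pixel of an axial slice
is represented by one square window per scale (default 48/28/12), all centered
on that pixel, stacked over the four MRI channels, and assigned the label of
the center pixel.

Even side lengths have no true center pixel; the convention throughout the
package is that the center sits at window index ``scale // 2``, i.e. the
window spans the half-open interval ``[c - scale//2, c + scale - scale//2)``.
With this convention the smaller scales are exact central crops of the larger
ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .errors import AlignmentError
from .phantom import axial_slices

logger = logging.getLogger(__name__)

#: sentinel returned by :func:`extract_patch` under the "skip" border policy
UNEXTRACTABLE = None

DEFAULT_SCALES = (48, 28, 12)


@dataclass
class PatchSample:
    """One multiscale stack of co-centered patches plus its center label."""

    patches: Dict[int, np.ndarray]
    center: Tuple[int, int, int]  # (case index or z, row, col) -- see PatchSet
    label: int


@dataclass
class SamplingPlan:
    """How to draw a training set: scales, per-class quotas, borders, seed."""

    scales: Tuple[int, ...] = DEFAULT_SCALES
    per_class_quota: Dict[int, int] = field(default_factory=lambda: {c: 500 for c in range(5)})
    border_policy: str = "reflect"
    seed: int = 0

    def __post_init__(self):
        if not self.scales:
            raise ValueError("scales must be non-empty")
        if any(q < 0 for q in self.per_class_quota.values()):
            raise ValueError("quotas must be >= 0")
        if self.border_policy not in ("reflect", "skip"):
            raise ValueError(f"unknown border policy: {self.border_policy}")


def _reflect_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Mirror-reflect out-of-range indices into [0, n) without edge repeat."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    m = np.mod(idx, period)
    return np.where(m < n, m, period - m)


def extract_patch(slice_stack: np.ndarray, center: Tuple[int, int], scale: int,
                  border_policy: str = "reflect"):
    """Extract the ``scale x scale`` multimodal window centered on ``center``.

    ``slice_stack`` is (H, W, C).  Out-of-bounds pixels are mirror-reflected
    under the default policy; under ``"skip"`` a window that does not fit
    returns the :data:`UNEXTRACTABLE` sentinel.
    """
    h, w = slice_stack.shape[:2]
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"center {center} outside slice of shape {(h, w)}")
    half = scale // 2
    rows = np.arange(r - half, r - half + scale)
    cols = np.arange(c - half, c - half + scale)
    if border_policy == "skip":
        if rows[0] < 0 or cols[0] < 0 or rows[-1] >= h or cols[-1] >= w:
            return UNEXTRACTABLE
    elif border_policy == "reflect":
        rows = _reflect_indices(rows, h)
        cols = _reflect_indices(cols, w)
    else:
        raise ValueError(f"unknown border policy: {border_policy}")
    return slice_stack[np.ix_(rows, cols)]


def extract_multiscale(slice_stack: np.ndarray, center, scales: Sequence[int],
                       border_policy: str = "reflect"):
    """Co-centered patches at every scale; None if any scale is unextractable."""
    out = {}
    for s in scales:
        p = extract_patch(slice_stack, center, s, border_policy)
        if p is UNEXTRACTABLE:
            return None
        out[s] = p
    return out


class PatchSet:
    """A training set of multiscale patches stored as stacked arrays.

    Sequence-like: ``len`` and integer indexing yield :class:`PatchSample`
    views.  Per-scale arrays are float32 of shape (n, scale, scale, 4).
    """

    def __init__(self, arrays: Dict[int, np.ndarray], labels: np.ndarray,
                 centers: np.ndarray):
        ns = {a.shape[0] for a in arrays.values()} | {len(labels), len(centers)}
        if len(ns) != 1:
            raise AlignmentError(f"inconsistent sample counts: {ns}")
        self.arrays = {int(s): np.asarray(a, dtype=np.float32) for s, a in arrays.items()}
        self.labels = np.asarray(labels, dtype=np.int64)
        self.centers = np.asarray(centers, dtype=np.int64)

    @property
    def scales(self):
        return tuple(sorted(self.arrays, reverse=True))

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, i: int) -> PatchSample:
        return PatchSample({s: self.arrays[s][i] for s in self.scales},
                           tuple(self.centers[i]), int(self.labels[i]))

    def scale_array(self, scale: int) -> np.ndarray:
        return self.arrays[int(scale)]

    def save_h5(self, path):
        """HDF5 layout: /patches/scale_<s>, /labels, /centers + scale attrs."""
        with h5py.File(path, "w") as f:
            g = f.create_group("patches")
            for s, a in self.arrays.items():
                g.create_dataset(f"scale_{s}", data=a, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("centers", data=self.centers)
            f.attrs["scales"] = list(self.scales)

    @classmethod
    def load_h5(cls, path) -> "PatchSet":
        with h5py.File(path, "r") as f:
            arrays = {int(k.split("_")[1]): f["patches"][k][...] for k in f["patches"]}
            return cls(arrays, f["labels"][...], f["centers"][...])


def _case_slices(case):
    """(volume, labels) -> list of (slice_stack, label_slice)."""
    vol, labels = case
    return list(axial_slices(vol, labels))


def sample_training_set(cases: Sequence, plan: SamplingPlan) -> PatchSet:
    """Draw a class-balanced multiscale patch set from labeled cases.

    Centers are drawn uniformly at random (without replacement) within each
    class mask across all cases.  A class whose mask holds fewer voxels than
    its quota is under-filled with a logged warning.  Reproducible under
    ``plan.seed``.
    """
    if not cases:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(plan.seed)
    stacks = []   # per case: (H, W, Z, 4)
    labvols = []
    for vol, labels in cases:
        if labels is None:
            raise ValueError("labels are required to sample a training set")
        if labels.shape != vol.shape:
            raise AlignmentError("case volume/label shape mismatch")
        stacks.append(vol.stack())
        labvols.append(labels.labels)

    max_scale = max(plan.scales)
    chosen = []  # (case, z, r, c, label)
    for cls in sorted(plan.per_class_quota):
        quota = plan.per_class_quota[cls]
        if quota == 0:
            continue
        cands = []
        for ci, lv in enumerate(labvols):
            idx = np.argwhere(lv == cls)
            if plan.border_policy == "skip":
                h, w = lv.shape[:2]
                half = max_scale // 2
                ok = ((idx[:, 0] >= half) & (idx[:, 0] < h - (max_scale - half) + 1)
                      & (idx[:, 1] >= half) & (idx[:, 1] < w - (max_scale - half) + 1))
                idx = idx[ok]
            if len(idx):
                cands.append(np.column_stack([np.full(len(idx), ci), idx]))
        cands = np.concatenate(cands, axis=0) if cands else np.empty((0, 4), dtype=int)
        if len(cands) < quota:
            logger.warning("class %d under-filled: %d available < quota %d",
                           cls, len(cands), quota)
        take = min(quota, len(cands))
        if take:
            sel = rng.choice(len(cands), size=take, replace=False)
            for row in cands[sel]:
                ci, r, c, z = int(row[0]), int(row[1]), int(row[2]), int(row[3])
                chosen.append((ci, z, r, c, cls))

    n = len(chosen)
    arrays = {s: np.empty((n, s, s, 4), dtype=np.float32) for s in plan.scales}
    labels_out = np.empty(n, dtype=np.int64)
    centers = np.empty((n, 3), dtype=np.int64)
    for i, (ci, z, r, c, cls) in enumerate(chosen):
        sl = stacks[ci][:, :, z, :]
        for s in plan.scales:
            arrays[s][i] = extract_patch(sl, (r, c), s, plan.border_policy)
        labels_out[i] = cls
        centers[i] = (z, r, c)
    return PatchSet(arrays, labels_out, centers)


def sample_patches_from_slices(slices: Sequence, per_class_quota: Dict[int, int],
                               scales: Sequence[int], rng: np.random.Generator,
                               border_policy: str = "reflect") -> PatchSet:
    """Balanced multiscale patch sample from a list of labeled 2D slices."""
    chosen = []
    for cls in sorted(per_class_quota):
        quota = per_class_quota[cls]
        if quota == 0:
            continue
        cands = []
        for si, (stack, lab) in enumerate(slices):
            idx = np.argwhere(lab == cls)
            if len(idx):
                cands.append(np.column_stack([np.full(len(idx), si), idx]))
        cands = np.concatenate(cands, axis=0) if cands else np.empty((0, 3), dtype=int)
        if len(cands) < quota:
            logger.warning("class %d under-filled: %d available < quota %d",
                           cls, len(cands), quota)
        take = min(quota, len(cands))
        if take:
            sel = rng.choice(len(cands), size=take, replace=False)
            for row in cands[sel]:
                chosen.append((int(row[0]), int(row[1]), int(row[2]), cls))

    n = len(chosen)
    arrays = {s: np.empty((n, s, s, 4), dtype=np.float32) for s in scales}
    labels_out = np.empty(n, dtype=np.int64)
    centers = np.empty((n, 3), dtype=np.int64)
    for i, (si, r, c, cls) in enumerate(chosen):
        stack, _ = slices[si]
        for s in scales:
            arrays[s][i] = extract_patch(stack, (r, c), s, border_policy)
        labels_out[i] = cls
        centers[i] = (si, r, c)
    return PatchSet(arrays, labels_out, centers)


def sample_slice_fraction(cases: Sequence, fraction: float, seed: int = 0):
    """Randomly select ``ceil(fraction * total)`` axial slices without replacement.

    This is the cheap pre-training sample (the prior scale-selection step uses
    1% of the training slices by default).  Returns a list of
    ``(slice_stack, label_slice)`` pairs; reproducible under ``seed``.
    """
    if not cases:
        raise ValueError("need at least one case")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    all_slices = []
    for case in cases:
        all_slices.extend(_case_slices(case))
    n_sel = math.ceil(fraction * len(all_slices))
    rng = np.random.default_rng(seed)
    sel = rng.choice(len(all_slices), size=n_sel, replace=False)
    return [all_slices[i] for i in sel]
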