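"""Multimodal volume containers and I/O in the formats BRATS 2013 uses.

A case is four co-registered scalar 3D channels (T1, T1c, T2, FLAIR) plus an
optional voxel-aligned integer label volume with codes 0 normal, 1 necrosis,
2 edema, 3 nonenhancing tumor, 4 enhancing tumor.  Volumes are read and
written as NIfTI (via nibabel) or MetaImage/MHA (via SimpleITK).

Axis convention: arrays are indexed (i, j, k) with the axial plane spanned by
the first two axes and k the through-plane (z) axis; all indices 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import AlignmentError, DegenerateInputError, FormatError

MODALITIES = ("t1", "t1c", "t2", "flair")

CODE_MAP = {0: "normal", 1: "necrosis", 2: "edema", 3: "nonenhancing", 4: "enhancing"}
VALID_LABELS = frozenset(CODE_MAP)


@dataclass
class MultimodalVolume:
    """Four co-registered scalar 3D channels plus voxel geometry metadata.

    ``channels`` maps modality name -> 3D float array; all four modalities in
    :data:`MODALITIES` must be present with one common shape.
    """

    channels: Mapping[str, np.ndarray]
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.channels]
        if missing:
            raise AlignmentError(f"missing modalities: {missing}")
        shapes = {m: self.channels[m].shape for m in MODALITIES}
        if len({s for s in shapes.values()}) != 1:
            raise AlignmentError(f"channel shapes disagree: {shapes}")
        if any(a.ndim != 3 for a in self.channels.values()):
            raise AlignmentError("channels must be 3D arrays")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.channels[MODALITIES[0]].shape

    def stack(self) -> np.ndarray:
        """Return channels as one (H, W, Z, 4) array in fixed modality order."""
        return np.stack([self.channels[m] for m in MODALITIES], axis=-1)

    @classmethod
    def from_stack(cls, arr: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        if arr.ndim != 4 or arr.shape[-1] != len(MODALITIES):
            raise AlignmentError(f"expected (H, W, Z, 4) stack, got {arr.shape}")
        return cls({m: np.ascontiguousarray(arr[..., i]) for i, m in enumerate(MODALITIES)},
                   spacing=tuple(spacing), origin=tuple(origin))


@dataclass
class LabelVolume:
    """Integer tissue-class volume with BRATS codes 0-4."""

    labels: np.ndarray
    code_map: Mapping[int, str] = field(default_factory=lambda: dict(CODE_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise AlignmentError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise FormatError("label volume contains non-integer values")
            self.labels = self.labels.astype(np.int16)
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise FormatError(f"label values outside {sorted(VALID_LABELS)}: {sorted(bad)}")

    @property
    def shape(self):
        return self.labels.shape


def _check_aligned(vol: MultimodalVolume, labels: Optional[LabelVolume]):
    if labels is not None and labels.shape != vol.shape:
        raise AlignmentError(f"labels shape {labels.shape} != volume shape {vol.shape}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _write_array(arr: np.ndarray, path: str, spacing, origin):
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(np.asarray(arr), affine), path)
    elif path.endswith(".mha"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(arr).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, path)
    else:
        raise FormatError(f"unsupported volume format: {path}")


def _read_array(path: str):
    path = str(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        arr = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        return arr, spacing, origin
    if path.endswith(".mha"):
        img = sitk.ReadImage(path)
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    raise FormatError(f"unsupported volume format: {path}")


def write_case(vol: MultimodalVolume, labels: Optional[LabelVolume], out_dir, *,
               fmt: str = "nifti", prefix: str = "") -> dict:
    """Write one case as one file per modality plus an optional label file.

    Returns the mapping of modality (and ``"labels"``) to the written path.
    Label files are always integer-typed.
    """
    if fmt not in ("nifti", "mha"):
        raise FormatError(f"unsupported format: {fmt}")
    ext = ".nii.gz" if fmt == "nifti" else ".mha"
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for m in MODALITIES:
        p = os.path.join(out_dir, f"{prefix}{m}{ext}")
        _write_array(vol.channels[m].astype(np.float32), p, vol.spacing, vol.origin)
        paths[m] = p
    if labels is not None:
        _check_aligned(vol, labels)
        p = os.path.join(out_dir, f"{prefix}labels{ext}")
        _write_array(labels.labels.astype(np.int16), p, vol.spacing, vol.origin)
        paths["labels"] = p
    return paths


def read_case(paths: Mapping[str, str], label_path: Optional[str] = None):
    """Read one case from per-modality file paths (+ optional label path).

    ``paths`` maps each modality in :data:`MODALITIES` to a NIfTI or MHA file;
    alternatively it may contain a ``"labels"`` key.  Shapes must already
    agree across modalities (no resampling is performed) and label values are
    validated against the BRATS code map.
    """
    label_path = label_path or paths.get("labels")
    channels = {}
    spacing = origin = None
    for m in MODALITIES:
        if m not in paths:
            raise IOError(f"missing path for modality {m!r}")
        arr, sp, og = _read_array(paths[m])
        channels[m] = np.asarray(arr, dtype=np.float32)
        if spacing is None:
            spacing, origin = sp, og
    vol = MultimodalVolume(channels, spacing=spacing, origin=origin)
    labels = None
    if label_path is not None:
        arr, _, _ = _read_array(label_path)
        labels = LabelVolume(np.asarray(arr))
        _check_aligned(vol, labels)
    return vol, labels


def case_paths(case_dir, fmt: str = "auto", prefix: str = "") -> dict:
    """Resolve the conventional per-modality file names inside ``case_dir``."""
    exts = {"nifti": [".nii.gz", ".nii"], "mha": [".mha"],
            "auto": [".nii.gz", ".nii", ".mha"]}[fmt]
    paths = {}
    for name in MODALITIES + ("labels",):
        for ext in exts:
            p = os.path.join(case_dir, f"{prefix}{name}{ext}")
            if os.path.exists(p):
                paths[name] = p
                break
    return paths


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

def normalize(vol: MultimodalVolume, method: str = "zscore") -> MultimodalVolume:
    """Per-channel, per-volume intensity normalization.

    MRI gray values are scanner-dependent, so the default ``zscore`` maps each
    channel's nonzero (brain) voxels to zero mean and unit standard deviation;
    exactly-zero (background) voxels are left untouched so the brain mask is
    preserved and the transform is idempotent.  ``method="none"`` returns the
    input unchanged.
    """
    if method == "none":
        return vol
    if method != "zscore":
        raise ValueError(f"unknown normalization method: {method}")
    out = {}
    for m in MODALITIES:
        ch = vol.channels[m].astype(np.float32, copy=True)
        mask = ch != 0
        if not mask.any():
            raise DegenerateInputError(f"channel {m} is all zero")
        vals = ch[mask]
        sd = float(vals.std())
        if sd < 1e-12:
            raise DegenerateInputError(f"channel {m} is constant over nonzero voxels")
        ch[mask] = (vals - float(vals.mean())) / sd
        out[m] = ch
    return MultimodalVolume(out, spacing=vol.spacing, origin=vol.origin)
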