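"""Synthetic multimodal brain phantom with BRATS-style tumor substructure.

The phantom is a brain ellipsoid inside an air background, containing a CSF
pocket and a tumor built from concentric spherical shells: necrotic core
(label 1), enhancing rim (label 4), nonenhancing shell (label 3) and edema
halo (label 2); everything else inside the brain is normal tissue (label 0).
Each of the four MRI channels (T1, T1c, T2, FLAIR) gets a per-tissue mean
intensity plus additive Gaussian noise inside the brain; air stays exactly 0.

Default means encode the modality contrasts a radiologist relies on: the
enhancing rim is brightest on T1/T1c (bright tumor border), all tumor tissue
is brighter than normal tissue on T2, and edema is bright on FLAIR while CSF
is suppressed, so FLAIR separates edema from CSF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import AlignmentError, ConfigurationError
from .volume_io import MODALITIES, LabelVolume, MultimodalVolume

logger = logging.getLogger(__name__)

#: per-tissue (T1, T1c, T2, FLAIR) mean intensities, arbitrary units
DEFAULT_MODALITY_MEANS = {
    0: (100.0, 100.0, 100.0, 100.0),   # normal brain tissue
    1: (70.0, 60.0, 160.0, 110.0),     # necrotic core: T1-dark, T2-bright
    2: (90.0, 80.0, 140.0, 150.0),     # edema: FLAIR-bright
    3: (80.0, 75.0, 130.0, 120.0),     # nonenhancing tumor
    4: (140.0, 160.0, 135.0, 125.0),   # enhancing rim: T1/T1c-bright border
    "csf": (60.0, 55.0, 180.0, 40.0),  # CSF: T2-bright, FLAIR-suppressed
}


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise of one synthetic case.

    All lengths are in voxels.  ``tumor_center`` may be an (i, j, k) triple or
    the string ``"random"`` (drawn so the whole tumor fits inside the brain).
    ``brain_z_radius`` optionally squashes the brain ellipsoid along z (the
    in-plane radius stays ``brain_radius``); tumor shells remain spherical and
    are clipped to the brain mask.
    """

    volume_shape: Tuple[int, int, int] = (64, 64, 64)
    brain_radius: float = 28.0
    tumor_center: Union[str, Tuple[float, float, float]] = "random"
    core_radius: float = 6.0
    enh_rim_width: float = 3.0
    nonenh_width: float = 3.0
    edema_width: float = 6.0
    modality_means: Mapping = field(default_factory=lambda: dict(DEFAULT_MODALITY_MEANS))
    noise_sd: float = 5.0
    csf_fraction: float = 0.004
    seed: int = 0
    brain_z_radius: Optional[float] = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ConfigurationError(f"volume_shape must be 3 positive ints, got {self.volume_shape}")
        self.volume_shape = shape
        widths = (self.core_radius, self.enh_rim_width, self.nonenh_width, self.edema_width)
        if any(w <= 0 for w in widths):
            raise ConfigurationError(f"all tumor radii/widths must be > 0, got {widths}")
        if self.tumor_radius >= self.brain_radius:
            raise ConfigurationError(
                f"tumor radius {self.tumor_radius} must be < brain radius {self.brain_radius}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.csf_fraction < 1.0:
            raise ConfigurationError("csf_fraction must be in [0, 1)")
        self._check_contrast()

    @property
    def tumor_radius(self) -> float:
        """Outer radius of the full tumor (through the edema halo)."""
        return self.core_radius + self.enh_rim_width + self.nonenh_width + self.edema_width

    @property
    def shell_radii(self) -> Tuple[float, float, float, float]:
        """Cumulative outer radii of (core, enhancing, nonenhancing, edema)."""
        r1 = self.core_radius
        r2 = r1 + self.enh_rim_width
        r3 = r2 + self.nonenh_width
        r4 = r3 + self.edema_width
        return (r1, r2, r3, r4)

    def _check_contrast(self):
        m = self.modality_means
        needed = [0, 1, 2, 3, 4, "csf"]
        missing = [k for k in needed if k not in m]
        if missing:
            raise ConfigurationError(f"modality_means missing entries: {missing}")
        t1 = {k: m[k][0] for k in (1, 2, 3, 4)}
        if not all(t1[4] > t1[k] for k in (1, 2, 3)):
            raise ConfigurationError("T1 mean of the enhancing rim (class 4) must exceed classes 1-3")
        if not all(m[k][2] > m[0][2] for k in (1, 2, 3, 4)):
            raise ConfigurationError("T2 means of tumor classes 1-4 must exceed normal tissue")
        if not m[2][3] > m["csf"][3]:
            raise ConfigurationError("FLAIR mean of edema (class 2) must exceed CSF")


def _brain_center(config: PhantomConfig) -> np.ndarray:
    return (np.asarray(config.volume_shape, dtype=float) - 1.0) / 2.0


def resolve_tumor_center(config: PhantomConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Concrete tumor center for ``config`` (draws from ``rng`` if "random")."""
    if isinstance(config.tumor_center, str):
        if config.tumor_center != "random":
            raise ConfigurationError(f"unknown tumor_center: {config.tumor_center}")
        if rng is None:
            rng = np.random.default_rng(config.seed)
        slack = config.brain_radius - config.tumor_radius - 1.0
        bz = config.brain_z_radius if config.brain_z_radius is not None else config.brain_radius
        zslack = max(0.0, min(slack, bz - 1.0))
        center = _brain_center(config)
        while True:
            off = rng.uniform(-1.0, 1.0, size=3) * (slack, slack, zslack)
            if (off[0] / max(slack, 1e-9)) ** 2 + (off[1] / max(slack, 1e-9)) ** 2 <= 1.0:
                return center + off
    return np.asarray(config.tumor_center, dtype=float)


def region_masks(config: PhantomConfig, tumor_center=None) -> dict:
    """Boolean masks for every tissue region of the phantom.

    Returns ``{"brain", "csf", "shells": {1: ..., 4: ..., 3: ..., 2: ...},
    "normal"}``.  ``normal`` is brain tissue that is neither tumor nor CSF.
    Deterministic given the config (the random tumor center replays the
    config seed).
    """
    if tumor_center is None:
        tumor_center = resolve_tumor_center(config)
    tumor_center = np.asarray(tumor_center, dtype=float)
    shape = config.volume_shape
    grid = np.indices(shape, dtype=np.float32)
    bc = _brain_center(config)
    bz = config.brain_z_radius if config.brain_z_radius is not None else config.brain_radius
    brain = ((grid[0] - bc[0]) / config.brain_radius) ** 2 \
        + ((grid[1] - bc[1]) / config.brain_radius) ** 2 \
        + ((grid[2] - bc[2]) / bz) ** 2 <= 1.0

    d2 = ((grid[0] - tumor_center[0]) ** 2
          + (grid[1] - tumor_center[1]) ** 2
          + (grid[2] - tumor_center[2]) ** 2)
    r1, r2, r3, r4 = config.shell_radii
    shells = {
        1: (d2 <= r1 ** 2) & brain,
        4: (d2 > r1 ** 2) & (d2 <= r2 ** 2) & brain,
        3: (d2 > r2 ** 2) & (d2 <= r3 ** 2) & brain,
        2: (d2 > r3 ** 2) & (d2 <= r4 ** 2) & brain,
    }
    tumor = d2 <= r4 ** 2

    csf = np.zeros(shape, dtype=bool)
    if config.csf_fraction > 0:
        r_csf = config.brain_radius * config.csf_fraction ** (1.0 / 3.0)
        gap = config.brain_radius - config.tumor_radius
        if r_csf > gap / 2.0 - 0.5:
            r_csf = max(1.0, gap / 2.0 - 0.5)
            logger.warning("CSF pocket shrunk to radius %.1f to fit between tumor and skull", r_csf)
        off = bc - tumor_center
        norm = float(np.linalg.norm(off[:2]))
        u = np.array([off[0] / norm, off[1] / norm, 0.0]) if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        dist = config.tumor_radius + r_csf + 1.0
        dist = min(dist, config.brain_radius - r_csf - 1.0)
        c_csf = tumor_center + u * dist
        rz = min(r_csf, max(1.0, bz - 1.0))
        e2 = ((grid[0] - c_csf[0]) / r_csf) ** 2 + ((grid[1] - c_csf[1]) / r_csf) ** 2 \
            + ((grid[2] - c_csf[2]) / rz) ** 2
        csf = (e2 <= 1.0) & brain & ~tumor

    normal = brain & ~tumor & ~csf
    return {"brain": brain, "csf": csf, "shells": shells, "normal": normal,
            "tumor_center": tumor_center}


def generate_phantom(config: PhantomConfig):
    """Generate one synthetic case.

    Returns ``(MultimodalVolume, LabelVolume)`` of identical shape.  Channel
    intensities are per-tissue means plus N(0, noise_sd^2) noise inside the
    brain; air is exactly zero.  Same seed, same config -> bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    center = resolve_tumor_center(config, rng)
    regions = region_masks(config, tumor_center=center)

    labels = np.zeros(config.volume_shape, dtype=np.int16)
    for lab, mask in regions["shells"].items():
        labels[mask] = lab

    means = config.modality_means
    channels = {}
    for ci, mod in enumerate(MODALITIES):
        ch = np.zeros(config.volume_shape, dtype=np.float32)
        ch[regions["normal"]] = means[0][ci]
        ch[regions["csf"]] = means["csf"][ci]
        for lab, mask in regions["shells"].items():
            ch[mask] = means[lab][ci]
        channels[mod] = ch
    if config.noise_sd > 0:
        brain = regions["brain"]
        n_brain = int(brain.sum())
        for mod in MODALITIES:
            noise = rng.normal(0.0, config.noise_sd, size=n_brain).astype(np.float32)
            channels[mod][brain] += noise

    vol = MultimodalVolume(channels)
    return vol, LabelVolume(labels)


def axial_slices(vol: MultimodalVolume, labels: Optional[LabelVolume] = None):
    """Iterate over all axial (x-y) planes in z index order.

    Yields ``(slice_stack, label_slice)`` where ``slice_stack`` is an
    (H, W, 4) array in (T1, T1c, T2, FLAIR) channel order and ``label_slice``
    is (H, W) ints (or None when no labels were given).
    """
    if labels is not None and labels.shape != vol.shape:
        raise AlignmentError(f"labels shape {labels.shape} != volume shape {vol.shape}")
    stack = vol.stack()
    for z in range(vol.shape[2]):
        lab = labels.labels[:, :, z] if labels is not None else None
        yield stack[:, :, z, :], lab
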