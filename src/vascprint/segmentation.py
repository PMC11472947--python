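"""Organ and vessel segmentation for contrast-perfused uCT volumes.

The workflow mirrors the standard whole-organ protocol: binarize the full
tissue with an inclusive intensity range, keep the largest connected object,
fill interior pores ("black speckles"), close, and measure the organ volume;
then, from the original grayscale image, denoise, binarize the vessels
(globally or with a locally adaptive threshold), restrict to the organ,
remove noise islands ("white speckles"), close, and measure the vascular
volume. Foreground connectivity is 26 and background (hole) connectivity 6
unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage

from .io_volumes import OrganConfig, VoxelVolume

__all__ = [
    "BinaryMask",
    "threshold_range",
    "keep_largest_component",
    "remove_speckles",
    "close_mask",
    "mask_volume",
    "denoise",
    "threshold_adaptive",
    "total_volume_pipeline",
    "vessel_pipeline",
    "ball_structure",
    "EmptyMaskError",
]

logger = logging.getLogger("vascprint")


class EmptyMaskError(ValueError):
    """Raised when a segmentation stage that requires foreground gets none."""


@dataclasses.dataclass
class BinaryMask:
    """A boolean 3-D segmentation on the grid of its source volume."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not (float(self.voxel_size_um) > 0):
            raise ValueError("voxel_size_um must be positive")
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


def ball_structure(radius: int) -> np.ndarray:
    """Discrete Euclidean ball: offsets with ||o||^2 <= radius^2."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz * zz + yy * yy + xx * xx) <= r * r


def threshold_range(vol: VoxelVolume, lo: float, hi: float) -> BinaryMask:
    """Binarize: foreground iff lo <= intensity <= hi (inclusive both ends)."""
    if lo > hi:
        raise ValueError(f"threshold lo {lo} > hi {hi}")
    data = (vol.data >= lo) & (vol.data <= hi)
    return BinaryMask(data=data, voxel_size_um=vol.voxel_size_um)


def keep_largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest connected component.

    Ties are broken deterministically toward the component whose first voxel
    comes first in C-order scan of the array.
    """
    if not mask.data.any():
        raise EmptyMaskError("cannot select largest component of an empty mask")
    labels, n = ndimage.label(mask.data, structure=_connectivity_structure(connectivity))
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    candidates = np.flatnonzero(sizes == sizes.max())
    if len(candidates) == 1:
        best = int(candidates[0])
    else:
        flat = labels.ravel()
        # the tied component encountered first in C-order scan wins
        best = int(flat[np.flatnonzero(np.isin(flat, candidates))[0]])
    return BinaryMask(data=labels == best, voxel_size_um=mask.voxel_size_um)


def remove_speckles(
    mask: BinaryMask,
    phase: str,
    min_size_voxels: int,
    connectivity: int | None = None,
) -> BinaryMask:
    """Despeckle: remove small foreground islands or fill small interior holes.

    ``phase="white"`` deletes foreground components smaller than
    ``min_size_voxels`` (default connectivity 26); ``phase="black"`` fills
    background components smaller than the limit (default connectivity 6),
    never touching background components that reach the volume border —
    exterior air is not a pore.
    """
    if min_size_voxels < 0:
        raise ValueError("min_size_voxels must be >= 0")
    if phase not in ("white", "black"):
        raise ValueError(f"phase must be 'white' or 'black', got {phase!r}")
    if min_size_voxels == 0:
        return BinaryMask(data=mask.data.copy(), voxel_size_um=mask.voxel_size_um)

    if phase == "white":
        conn = 26 if connectivity is None else connectivity
        labels, _ = ndimage.label(mask.data, structure=_connectivity_structure(conn))
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size_voxels
        keep[0] = False
        return BinaryMask(data=keep[labels], voxel_size_um=mask.voxel_size_um)

    conn = 6 if connectivity is None else connectivity
    bg = ~mask.data
    labels, n = ndimage.label(bg, structure=_connectivity_structure(conn))
    if n == 0:
        return BinaryMask(data=mask.data.copy(), voxel_size_um=mask.voxel_size_um)
    sizes = np.bincount(labels.ravel())
    border_labels = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ]))
    fill = sizes < min_size_voxels
    fill[0] = False
    fill[border_labels] = False
    return BinaryMask(data=mask.data | fill[labels], voxel_size_um=mask.voxel_size_um)


def close_mask(mask: BinaryMask, radius_voxels: int) -> BinaryMask:
    """Morphological closing with a discrete Euclidean ball.

    The mask is padded before dilation so the operation equals the closing in
    an unbounded background, which makes it extensive (output superset of
    input) including at the volume border.
    """
    if radius_voxels < 0:
        raise ValueError("radius_voxels must be >= 0")
    r = int(radius_voxels)
    if r == 0 or not mask.data.any():
        return BinaryMask(data=mask.data.copy(), voxel_size_um=mask.voxel_size_um)
    structure = ball_structure(r)
    padded = np.pad(mask.data, r, mode="constant", constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=structure)
    closed = ndimage.binary_erosion(dilated, structure=structure, border_value=0)
    closed = closed[r:-r, r:-r, r:-r]
    return BinaryMask(data=closed, voxel_size_um=mask.voxel_size_um)


def mask_volume(mask: BinaryMask) -> float:
    """Foreground volume in mm^3: voxel count x (voxel_size_um / 1000)^3."""
    return mask.count() * (mask.voxel_size_um / 1000.0) ** 3


def denoise(vol: VoxelVolume, kind: str, size: float) -> VoxelVolume:
    """Smooth a volume before vessel binarization.

    ``gaussian`` uses ``size`` as the sigma in voxels; ``median`` uses
    ``size`` as the window half-width in voxels (size 1 -> 3x3x3 window);
    ``none`` is the identity.
    """
    if kind == "none":
        return VoxelVolume(vol.data.copy(), vol.voxel_size_um, vol.provenance)
    if kind == "gaussian":
        if not size > 0:
            raise ValueError("gaussian sigma must be positive")
        out = ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=size)
        if np.issubdtype(vol.data.dtype, np.integer):
            info = np.iinfo(vol.data.dtype)
            out = np.clip(np.rint(out), info.min, info.max).astype(vol.data.dtype)
        return VoxelVolume(out, vol.voxel_size_um, vol.provenance)
    if kind == "median":
        half = int(size)
        if half < 1:
            raise ValueError("median half-width must be >= 1")
        out = ndimage.median_filter(vol.data, size=2 * half + 1, mode="nearest")
        return VoxelVolume(out, vol.voxel_size_um, vol.provenance)
    raise ValueError(f"unknown denoise kind {kind!r}")


def threshold_adaptive(
    vol: VoxelVolume, window_radius_voxels: int, offset: float
) -> BinaryMask:
    """Local-mean adaptive threshold.

    A voxel is foreground iff its intensity is at least the mean over the
    cubic window of half-width ``window_radius_voxels`` centred on it
    (the window is clipped at the volume borders) plus ``offset``.
    """
    if window_radius_voxels < 1:
        raise ValueError("window_radius_voxels must be >= 1")
    w = 2 * int(window_radius_voxels) + 1
    img = vol.data.astype(np.float64)
    # mean over the clipped window: windowed sum / in-bounds voxel count
    sums = ndimage.uniform_filter(img, size=w, mode="constant", cval=0.0) * w**3
    counts = ndimage.uniform_filter(
        np.ones_like(img), size=w, mode="constant", cval=0.0
    ) * w**3
    local_mean = sums / counts
    data = img >= local_mean + offset
    return BinaryMask(data=data, voxel_size_um=vol.voxel_size_um)


def total_volume_pipeline(
    vol: VoxelVolume, cfg: OrganConfig
) -> tuple[BinaryMask, float]:
    """Total-organ mask and volume.

    Composition, in exactly this order: inclusive range threshold ->
    largest-component selection -> black-speckle (pore) filling ->
    closing -> volume measurement.
    """
    lo, hi = cfg.total_threshold
    mask = threshold_range(vol, lo, hi)
    if not mask.data.any():
        raise EmptyMaskError("total-volume threshold produced an empty mask")
    logger.info("total: threshold [%s, %s] -> %d voxels", lo, hi, mask.count())
    mask = keep_largest_component(mask)
    logger.info("total: largest component -> %d voxels", mask.count())
    mask = remove_speckles(mask, "black", cfg.black_speckle_min_voxels)
    logger.info("total: black despeckle -> %d voxels", mask.count())
    mask = close_mask(mask, cfg.closing_radius_voxels)
    logger.info("total: closing r=%d -> %d voxels", cfg.closing_radius_voxels,
                mask.count())
    return mask, mask_volume(mask)


def vessel_pipeline(
    vol: VoxelVolume, organ_mask: BinaryMask, cfg: OrganConfig
) -> tuple[BinaryMask, float]:
    """Vessel mask and vascular volume inside a previously segmented organ.

    Composition: denoise -> vessel threshold (global range or local-mean
    adaptive) -> intersection with the organ mask -> white despeckle ->
    closing -> volume. The intersection guarantees vessel mask is a subset of
    the organ mask, excluding bright material outside the tissue (e.g. the
    wrapping foil). An empty vessel mask is a valid outcome (failed
    perfusion) and is reported with a warning rather than an exception.
    """
    if organ_mask.shape != vol.shape:
        raise ValueError(
            f"grid mismatch: organ mask {organ_mask.shape} vs volume {vol.shape}"
        )
    smoothed = denoise(vol, cfg.filter_kind, cfg.filter_size)
    mode = cfg.vessel_threshold_mode
    if mode[0] == "global":
        vessels = threshold_range(smoothed, mode[1], mode[2])
    else:
        vessels = threshold_adaptive(smoothed, int(mode[1]), mode[2])
    logger.info("vessels: threshold (%s) -> %d voxels", mode[0], vessels.count())
    vessels = BinaryMask(vessels.data & organ_mask.data, vessels.voxel_size_um)
    logger.info("vessels: organ intersection -> %d voxels", vessels.count())
    vessels = remove_speckles(vessels, "white", cfg.white_speckle_min_voxels)
    logger.info("vessels: white despeckle -> %d voxels", vessels.count())
    vessels = close_mask(vessels, cfg.closing_radius_voxels)
    # closing may leak outside the organ by up to the closing radius; clip back
    vessels = BinaryMask(vessels.data & organ_mask.data, vessels.voxel_size_um)
    logger.info("vessels: closing r=%d -> %d voxels", cfg.closing_radius_voxels,
                vessels.count())
    if not vessels.data.any():
        warnings.warn("vessel mask is empty (failed perfusion?)", stacklevel=2)
    return vessels, mask_volume(vessels)
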