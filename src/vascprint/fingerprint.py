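"""The vascular fingerprint: diameter-binned vascular volume distribution.

Each vessel voxel contributes one voxel volume to the diameter bin containing
its local-thickness value. Bins are uniform and half-open, ``(edge - w,
edge]``, labelled by their upper edge, so that the diameter cap (default
400 um, i.e. "vessels up to 0.4 mm") is an exact bin boundary. The summed
volume of all vessels at or below the cap defines the organ's total vascular
volume (100%); voxels thicker than the cap are tracked separately and do not
enter the denominator. Per-bin volume fractions of this total are the
organ-characteristic "vascular fingerprint".
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_volumes import OrganConfig, VoxelVolume
from .segmentation import (
    BinaryMask,
    mask_volume,
    total_volume_pipeline,
    vessel_pipeline,
)
from .thickness import ThicknessMap, local_thickness

__all__ = [
    "Fingerprint",
    "FingerprintSummary",
    "GroupFingerprint",
    "diameter_histogram",
    "summarize",
    "aggregate_group",
    "compare_fingerprints",
    "analyze_organ",
]


@dataclasses.dataclass
class Fingerprint:
    """Diameter-binned vascular volume, normalized to the <=cap total."""

    bin_upper_edges_um: np.ndarray
    bin_volumes_mm3: np.ndarray
    bin_fractions_pct: np.ndarray
    total_vascular_volume_mm3: float
    diameter_cap_um: float
    excluded_volume_mm3: float

    def __post_init__(self) -> None:
        self.bin_upper_edges_um = np.asarray(self.bin_upper_edges_um, dtype=float)
        self.bin_volumes_mm3 = np.asarray(self.bin_volumes_mm3, dtype=float)
        self.bin_fractions_pct = np.asarray(self.bin_fractions_pct, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_upper_um": self.bin_upper_edges_um,
            "volume_mm3": self.bin_volumes_mm3,
            "fraction_pct": self.bin_fractions_pct,
        })


@dataclasses.dataclass
class FingerprintSummary:
    """Headline per-organ statistics of a fingerprint.

    ``peak_diameter_um`` is the upper edge of the fullest bin (ties broken
    toward the smaller diameter); ``half_volume_diameter_um`` is the smallest
    upper edge at which the cumulative fraction reaches 50%.
    """

    organ_name: str
    peak_diameter_um: float
    peak_fraction_pct: float
    half_volume_diameter_um: float
    total_vascular_volume_mm3: float
    total_organ_volume_mm3: float
    vascular_fraction_pct: float


@dataclasses.dataclass
class GroupFingerprint:
    """Per-bin mean and sample standard deviation across subjects."""

    bin_upper_edges_um: np.ndarray
    mean_fraction_pct: np.ndarray
    sd_fraction_pct: Optional[np.ndarray]  # None when n = 1
    n: int


def diameter_histogram(
    thick: ThicknessMap,
    vessels: BinaryMask,
    bin_width_um: float,
    cap_um: float,
) -> Fingerprint:
    """Bin vessel-voxel volumes by local diameter.

    Bin k spans diameters ``((k-1) w, k w]``; voxels with thickness above
    ``cap_um`` accumulate in ``excluded_volume_mm3`` and are left out of the
    100% normalization. Volume is conserved exactly: binned plus excluded
    volume equals the vessel-mask volume.
    """
    if thick.shape != vessels.shape:
        raise ValueError("thickness map and vessel mask grids differ")
    ratio = cap_um / bin_width_um
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("cap_um must be an integer multiple of bin_width_um")
    n_bins = int(round(ratio))

    t = thick.data[vessels.data]
    voxel_mm3 = (vessels.voxel_size_um / 1000.0) ** 3
    # half-open (edge - w, edge]: value exactly on an edge goes to that bin
    idx = np.ceil(t / bin_width_um - 1e-9).astype(np.int64)
    idx = np.maximum(idx, 1)
    over = idx > n_bins
    counts = np.bincount(idx[~over], minlength=n_bins + 1)[1:n_bins + 1]
    volumes = counts * voxel_mm3
    excluded = int(over.sum()) * voxel_mm3
    total = float(volumes.sum())
    if total <= 0:
        raise ValueError("zero vascular volume at or below the diameter cap")
    edges = bin_width_um * np.arange(1, n_bins + 1)
    fractions = 100.0 * volumes / total
    return Fingerprint(
        bin_upper_edges_um=edges,
        bin_volumes_mm3=volumes,
        bin_fractions_pct=fractions,
        total_vascular_volume_mm3=total,
        diameter_cap_um=float(cap_um),
        excluded_volume_mm3=float(excluded),
    )


def summarize(
    fp: Fingerprint, total_organ_volume_mm3: float, organ_name: str = ""
) -> FingerprintSummary:
    """Peak bin, half-volume diameter, and vascular fraction of the organ."""
    if not total_organ_volume_mm3 > 0:
        raise ValueError("total organ volume must be positive")
    peak_i = int(np.argmax(fp.bin_fractions_pct))  # first maximum: smaller diameter
    cum = np.cumsum(fp.bin_fractions_pct)
    half_i = int(np.argmax(cum >= 50.0 - 1e-9))
    return FingerprintSummary(
        organ_name=organ_name,
        peak_diameter_um=float(fp.bin_upper_edges_um[peak_i]),
        peak_fraction_pct=float(fp.bin_fractions_pct[peak_i]),
        half_volume_diameter_um=float(fp.bin_upper_edges_um[half_i]),
        total_vascular_volume_mm3=fp.total_vascular_volume_mm3,
        total_organ_volume_mm3=float(total_organ_volume_mm3),
        vascular_fraction_pct=100.0 * fp.total_vascular_volume_mm3
        / total_organ_volume_mm3,
    )


def _check_same_bins(fps: Sequence[Fingerprint]) -> np.ndarray:
    edges = fps[0].bin_upper_edges_um
    for fp in fps[1:]:
        if fp.bin_upper_edges_um.shape != edges.shape or not np.allclose(
            fp.bin_upper_edges_um, edges
        ):
            raise ValueError("fingerprints have mismatched bin edges")
    return edges


def aggregate_group(fps: Sequence[Fingerprint]) -> GroupFingerprint:
    """Per-bin mean and sample (n-1) standard deviation across subjects."""
    if len(fps) == 0:
        raise ValueError("empty fingerprint list")
    edges = _check_same_bins(fps)
    fractions = np.stack([fp.bin_fractions_pct for fp in fps])
    mean = fractions.mean(axis=0)
    sd = fractions.std(axis=0, ddof=1) if len(fps) > 1 else None
    return GroupFingerprint(
        bin_upper_edges_um=edges, mean_fraction_pct=mean,
        sd_fraction_pct=sd, n=len(fps),
    )


def compare_fingerprints(
    test: Fingerprint, reference: Fingerprint
) -> tuple[np.ndarray, float]:
    """Per-bin fraction differences (test - reference) and their summed
    absolute value as a scalar divergence."""
    _check_same_bins([test, reference])
    diff = test.bin_fractions_pct - reference.bin_fractions_pct
    return diff, float(np.abs(diff).sum())


def analyze_organ(
    vol: VoxelVolume, cfg: OrganConfig
) -> tuple[FingerprintSummary, Fingerprint, dict]:
    """End-to-end organ analysis.

    Total-organ segmentation, vessel segmentation, local thickness, diameter
    histogram, summary — composed in that order. Returns the summary, the
    fingerprint, and a dict with the ``organ`` and ``vessels`` masks and the
    ``thickness`` map.
    """
    organ_mask, organ_volume = total_volume_pipeline(vol, cfg)
    vessel_mask, vascular_volume = vessel_pipeline(vol, organ_mask, cfg)
    thick = local_thickness(vessel_mask)
    fp = diameter_histogram(
        thick, vessel_mask,
        bin_width_um=cfg.resolve_bin_width(vol.voxel_size_um),
        cap_um=cfg.diameter_cap_um,
    )
    summary = summarize(fp, organ_volume, organ_name=cfg.organ_name)
    masks = {"organ": organ_mask, "vessels": vessel_mask, "thickness": thick}
    return summary, fp, masks
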