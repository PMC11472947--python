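"""Volumetric image I/O and per-organ analysis configuration.

All volumes are 3-D arrays in a fixed (slice, row, column) axis order with an
isotropic voxel size in micrometres. Supported on-disk formats are multi-page
TIFF stacks (or a directory of numbered single-slice TIFFs) and NIfTI-1; for
NIfTI the header zooms are interpreted as micrometres per voxel. Binary masks
are serialized as 8-bit images with foreground 255 and background 0.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import nibabel as nib
import tifffile
import yaml

__all__ = [
    "VoxelVolume",
    "OrganConfig",
    "read_volume",
    "write_volume",
    "load_config",
    "organ_config_preset",
    "CONFIG_PRESETS",
]


@dataclasses.dataclass
class VoxelVolume:
    """A 3-D grayscale image with isotropic voxel size.

    Attributes
    ----------
    data : numpy.ndarray
        3-D scalar grid, axes ordered (slice, row, column).
    voxel_size_um : float
        Isotropic edge length of a voxel in micrometres.
    provenance : str
        Free-text label describing where the volume came from.
    """

    data: np.ndarray
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not (float(self.voxel_size_um) > 0):
            raise ValueError("voxel_size_um must be positive")
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple:
        return self.data.shape


# Tolerance for declaring header spacings isotropic (relative).
_ISO_RTOL = 1e-3


def _read_tiff_dir(path: Path) -> np.ndarray:
    slices = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    if not slices:
        raise IOError(f"no TIFF slices found in directory {path}")
    pages = [tifffile.imread(str(p)) for p in slices]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise IOError("slice images in directory have inconsistent shapes")
    return np.stack(pages, axis=0)


def read_volume(path: os.PathLike | str, voxel_size_um: Optional[float] = None) -> VoxelVolume:
    """Read a TIFF stack or NIfTI-1 file into a :class:`VoxelVolume`.

    The voxel size is taken from the file header when the format carries one
    (NIfTI); otherwise the ``voxel_size_um`` argument is required. Anisotropic
    headers are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")

    if path.is_dir():
        data = _read_tiff_dir(path)
        header_vs = None
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        header_vs = None
    elif path.suffix.lower() == ".nii" or path.name.lower().endswith(".nii.gz"):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=_ISO_RTOL):
            raise ValueError(f"anisotropic voxels {tuple(zooms)} are not supported")
        header_vs = float(zooms[0]) if zooms[0] > 0 else None
        # NIfTI arrays are (x, y, z); bring them to (slice, row, column).
        data = np.asarray(img.dataobj).transpose(2, 1, 0)
    else:
        raise IOError(f"unrecognized volume format: {path.suffix!r}")

    vs = header_vs if header_vs is not None else voxel_size_um
    if vs is None:
        raise ValueError("voxel size absent from both header and argument")
    return VoxelVolume(data=data, voxel_size_um=vs, provenance=str(path))


def write_volume(vol: VoxelVolume, path: os.PathLike | str) -> None:
    """Write a volume as multi-page TIFF or NIfTI-1 (chosen by extension).

    Boolean grids are stored as 8-bit {0, 255}. NIfTI headers carry the voxel
    size (in micrometres) in the zooms; TIFF does not store it.
    """
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = (data.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), data)
    elif path.suffix.lower() == ".nii" or path.name.lower().endswith(".nii.gz"):
        affine = np.diag([vol.voxel_size_um] * 3 + [1.0])
        img = nib.Nifti1Image(data.transpose(2, 1, 0), affine, dtype=data.dtype)
        img.header.set_zooms((vol.voxel_size_um,) * 3)
        nib.save(img, str(path))
    else:
        raise IOError(f"unrecognized volume format: {path.suffix!r}")


@dataclasses.dataclass
class OrganConfig:
    """Per-organ parameterization of the segmentation/quantification pipeline.

    ``total_threshold`` is the inclusive intensity range selecting the whole
    organ (tissue plus contrast agent); ``vessel_threshold_mode`` is either
    ``("global", lo, hi)`` or ``("adaptive", window_radius_voxels, offset)``.
    The per-organ numeric values bundled as presets are calibration points to
    be tuned on real scans, not measured constants; only the global/adaptive
    mode split per organ is grounded in practice.
    """

    organ_name: str
    total_threshold: tuple[float, float]
    vessel_threshold_mode: tuple
    black_speckle_min_voxels: int = 0
    white_speckle_min_voxels: int = 0
    closing_radius_voxels: int = 0
    filter_kind: str = "none"          # gaussian | median | none
    filter_size: float = 0.0
    diameter_cap_um: float = 400.0
    bin_width_um: Optional[float] = None  # default: 2 x voxel size, resolved at use

    def __post_init__(self) -> None:
        lo, hi = self.total_threshold
        if lo > hi:
            raise ValueError(f"total_threshold lo > hi: {self.total_threshold}")
        mode = self.vessel_threshold_mode[0]
        if mode == "global":
            _, vlo, vhi = self.vessel_threshold_mode
            if vlo > vhi:
                raise ValueError("vessel threshold lo > hi")
        elif mode == "adaptive":
            _, radius, _offset = self.vessel_threshold_mode
            if int(radius) < 1:
                raise ValueError("adaptive window radius must be >= 1")
        else:
            raise ValueError(f"unknown vessel_threshold_mode {mode!r}")
        if self.filter_kind not in ("gaussian", "median", "none"):
            raise ValueError(f"unknown filter_kind {self.filter_kind!r}")
        for name in ("black_speckle_min_voxels", "white_speckle_min_voxels",
                     "closing_radius_voxels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.diameter_cap_um > 0:
            raise ValueError("diameter_cap_um must be positive")
        if self.bin_width_um is not None:
            self._check_cap_multiple(self.bin_width_um)

    def _check_cap_multiple(self, width: float) -> None:
        ratio = self.diameter_cap_um / width
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"diameter_cap_um {self.diameter_cap_um} is not a multiple of "
                f"bin width {width}"
            )

    def resolve_bin_width(self, voxel_size_um: float) -> float:
        """Bin width to use: configured value, else 2 x voxel size."""
        if self.bin_width_um is not None:
            return self.bin_width_um
        width = 2.0 * voxel_size_um
        self._check_cap_multiple(width)
        return width


# Bundled presets. Intensity thresholds assume 8-bit scans; despeckle sizes
# and closing radii are starting points for calibration on real data. The
# global/adaptive split follows reported practice: homogeneous vessel-size
# distributions (brain, and by extension tongue/eye) segment well globally,
# while organs with regionally dominant large or small vessels (heart,
# kidney) need a locally adaptive threshold.
CONFIG_PRESETS: dict[str, dict] = {
    "brain": dict(
        total_threshold=(30, 255), vessel_threshold_mode=("global", 100, 255),
        black_speckle_min_voxels=125, white_speckle_min_voxels=27,
        closing_radius_voxels=2, filter_kind="gaussian", filter_size=1.0,
    ),
    "tongue": dict(
        total_threshold=(30, 255), vessel_threshold_mode=("global", 100, 255),
        black_speckle_min_voxels=125, white_speckle_min_voxels=27,
        closing_radius_voxels=2, filter_kind="gaussian", filter_size=1.0,
    ),
    "eye": dict(
        total_threshold=(25, 255), vessel_threshold_mode=("global", 90, 255),
        black_speckle_min_voxels=64, white_speckle_min_voxels=27,
        closing_radius_voxels=2, filter_kind="gaussian", filter_size=1.0,
    ),
    "heart": dict(
        total_threshold=(30, 255), vessel_threshold_mode=("adaptive", 8, 20),
        black_speckle_min_voxels=125, white_speckle_min_voxels=27,
        closing_radius_voxels=2, filter_kind="median", filter_size=1,
    ),
    "kidney": dict(
        total_threshold=(30, 255), vessel_threshold_mode=("adaptive", 8, 20),
        black_speckle_min_voxels=125, white_speckle_min_voxels=27,
        closing_radius_voxels=2, filter_kind="median", filter_size=1,
    ),
}


def organ_config_preset(name: str) -> OrganConfig:
    """Return the bundled :class:`OrganConfig` preset for an organ."""
    if name not in CONFIG_PRESETS:
        raise KeyError(f"unknown organ preset {name!r}; "
                       f"known: {sorted(CONFIG_PRESETS)}")
    params = dict(CONFIG_PRESETS[name])
    mode = params.pop("vessel_threshold_mode")
    return OrganConfig(organ_name=name, vessel_threshold_mode=tuple(mode), **params)


_MANDATORY = ("total_threshold", "vessel_threshold_mode")


def load_config(path: os.PathLike | str) -> OrganConfig:
    """Load and validate an :class:`OrganConfig` from a YAML file.

    Mandatory keys: ``total_threshold`` (two-element list) and
    ``vessel_threshold_mode`` (``[global, lo, hi]`` or
    ``[adaptive, window_radius_voxels, offset]``). Everything else takes the
    documented defaults, in particular a 400 um diameter cap.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} is not a mapping")
    for key in _MANDATORY:
        if key not in raw:
            raise ValueError(f"config missing mandatory field {key!r}")
    kwargs = dict(raw)
    kwargs.setdefault("organ_name", Path(path).stem)
    kwargs["total_threshold"] = tuple(kwargs["total_threshold"])
    kwargs["vessel_threshold_mode"] = tuple(kwargs["vessel_threshold_mode"])
    known = {f.name for f in dataclasses.fields(OrganConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return OrganConfig(**kwargs)
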