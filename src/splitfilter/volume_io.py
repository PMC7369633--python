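"""Reading, writing and validation of MRC density volumes.

Maps are handled in the MRC2014 format. Input may be any of the common
real-valued on-disk modes (0, 1, 2, 6); output is always mode 2 (32-bit
IEEE float), the format the filter operates on. Axes are kept in the
file's native section/row/column order and never permuted: both half maps
and the mask come from the same reconstruction program, so only their
relative consistency matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import mrcfile
import numpy as np

__all__ = [
    "DensityVolume",
    "MaskVolume",
    "HalfMapPair",
    "read_volume",
    "read_mask",
    "write_volume",
    "validate_pair",
    "spherical_mask",
]

#: MRC modes accepted on input (int8, int16, float32, uint16).
_ACCEPTED_MODES = (0, 1, 2, 6)

#: Mask values may stray outside [0,1] by this much before being an error.
_MASK_CLAMP_TOL = 1e-6


class VolumeError(ValueError):
    """Raised for malformed or mutually incompatible volumes."""


@dataclass
class DensityVolume:
    """A real-valued scalar field on a cubic voxel grid.

    Parameters
    ----------
    data
        3-D array of densities (arbitrary units). Stored as float64.
    voxel_size
        Edge length of one voxel in ångström.
    origin
        MRC origin record in ångström. Preserved through I/O but never
        used in any computation.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3-D grid, got shape {self.data.shape}")
        nx, ny, nz = self.data.shape
        if not (nx == ny == nz):
            raise VolumeError(f"grid must be cubic, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains NaN or Inf voxels")
        if not (self.voxel_size > 0):
            raise VolumeError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def box_size(self) -> int:
        return self.data.shape[0]


@dataclass
class MaskVolume(DensityVolume):
    """A weight field in [0, 1] delimiting the region of interest.

    Values within ±1e-6 of the interval are clamped; larger excursions
    are rejected. At least one voxel must exceed 0.5 so the mask has a
    non-empty interior.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        lo, hi = self.data.min(), self.data.max()
        if lo < -_MASK_CLAMP_TOL or hi > 1.0 + _MASK_CLAMP_TOL:
            raise VolumeError(
                f"mask values must lie in [0,1]; found range [{lo:g}, {hi:g}]"
            )
        np.clip(self.data, 0.0, 1.0, out=self.data)
        if not np.any(self.data > 0.5):
            raise VolumeError("mask has no interior (no voxel above 0.5)")

    @property
    def interior(self) -> np.ndarray:
        """Boolean interior (mask > 0.5), the domain of all voxel statistics."""
        return self.data > 0.5


@dataclass
class HalfMapPair:
    """Two half maps plus their shared mask — the unit the filter operates on."""

    half1: DensityVolume
    half2: DensityVolume
    mask: MaskVolume = field(repr=False)

    @property
    def box_size(self) -> int:
        return self.half1.box_size

    @property
    def voxel_size(self) -> float:
        return self.half1.voxel_size


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC volume into a :class:`DensityVolume`.

    Modes 0/1/2/6 are converted to float64; the voxel size and origin are
    taken from the header. Non-cubic grids and non-finite voxels are
    rejected.
    """
    path = Path(path)
    try:
        with mrcfile.open(path, permissive=True) as mrc:
            mode = int(mrc.header.mode)
            if mode not in _ACCEPTED_MODES:
                raise VolumeError(f"{path}: unsupported MRC mode {mode}")
            data = np.asarray(mrc.data, dtype=np.float64)
            vx = float(mrc.voxel_size.x) if mrc.voxel_size.x > 0 else 1.0
            origin = (
                float(mrc.header.origin.x),
                float(mrc.header.origin.y),
                float(mrc.header.origin.z),
            )
    except VolumeError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the path in the message
        raise OSError(f"could not read MRC file {path}: {exc}") from exc
    return DensityVolume(data=data, voxel_size=vx, origin=origin)


def read_mask(path: str | Path) -> MaskVolume:
    """Read an MRC volume and validate it as a mask."""
    vol = read_volume(path)
    return MaskVolume(data=vol.data, voxel_size=vol.voxel_size, origin=vol.origin)


def write_volume(vol: DensityVolume, path: str | Path) -> None:
    """Write a volume as MRC mode 2 with correct header statistics."""
    path = Path(path)
    try:
        with mrcfile.new(path, overwrite=True) as mrc:
            mrc.set_data(vol.data.astype(np.float32))
            mrc.voxel_size = vol.voxel_size
            mrc.header.origin.x = vol.origin[0]
            mrc.header.origin.y = vol.origin[1]
            mrc.header.origin.z = vol.origin[2]
            mrc.update_header_stats()
    except OSError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not write MRC file {path}: {exc}") from exc


def validate_pair(
    v1: DensityVolume, v2: DensityVolume, mask: MaskVolume
) -> HalfMapPair:
    """Bundle two half maps and a mask after checking grid compatibility.

    All three volumes must share the box size exactly and the voxel size
    to 1e-4 relative tolerance. Symmetric in the two half maps.
    """
    for name, vol in (("half2", v2), ("mask", mask)):
        if vol.box_size != v1.box_size:
            raise VolumeError(
                f"box_size mismatch: half1 is {v1.box_size}, {name} is {vol.box_size}"
            )
        if abs(vol.voxel_size - v1.voxel_size) > 1e-4 * v1.voxel_size:
            raise VolumeError(
                f"voxel_size mismatch: half1 is {v1.voxel_size} Å, "
                f"{name} is {vol.voxel_size} Å"
            )
    return HalfMapPair(half1=v1, half2=v2, mask=mask)


def spherical_mask(
    box_size: int,
    voxel_size: float = 1.0,
    radius_frac: float = 0.45,
    soft_edge: float = 3.0,
) -> MaskVolume:
    """Centred soft spherical mask, the fallback when the user provides none.

    The radius defaults to 0.45 of the box edge with a cosine-shaped
    soft edge of ``soft_edge`` voxels.
    """
    r = np.indices((box_size,) * 3, dtype=np.float64)
    centre = (box_size - 1) / 2.0
    dist = np.sqrt(((r - centre) ** 2).sum(axis=0))
    radius = radius_frac * box_size
    mask = np.ones((box_size,) * 3)
    if soft_edge > 0:
        edge = (dist - (radius - soft_edge)) / soft_edge
        mask = np.where(
            dist <= radius - soft_edge,
            1.0,
            np.where(dist >= radius, 0.0, 0.5 * (1.0 + np.cos(np.pi * edge))),
        )
    else:
        mask = (dist <= radius).astype(np.float64)
    return MaskVolume(data=mask, voxel_size=voxel_size)
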