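"""Synthetic phantoms with a known, stepped local-resolution structure.

The generator emulates the statistical structure of a multi-subunit
particle whose subunits have distinct local resolutions: random
Gaussian blobs are placed in disjoint angular sectors of a ring, each
sector's density is truncated to its own spatial frequency with the
same eighth-order Butterworth low-pass the filter uses, and the sectors
are summed. Two independent Gaussian noise fields then produce a
half-map pair. Ground truth, per-sector masks and all random draws are
fully determined by the spec's single seed.

The default truncation frequencies step through 0.0125, 0.025, 0.05,
0.1, 0.2 and 0.35 cycles/voxel — a defined local resolution gradient
around the ring spanning nearly the whole accessible frequency range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import shell_math as sm
from .volume_io import DensityVolume, HalfMapPair, MaskVolume

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "sector_fields",
    "ring_mask",
    "make_half_pair",
    "plant_correlated_artefact",
    "masked_region_fsc",
]

#: Stepped per-sector truncation frequencies (cycles/voxel).
DEFAULT_TRUNCATIONS = (0.0125, 0.025, 0.05, 0.1, 0.2, 0.35)

_SOFT_EDGE = 3.0  # voxels, cosine edge width of all generated masks


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic phantom.

    ``subunit_truncations`` are spatial frequencies in cycles/voxel,
    one per angular sector; ``noise_sigma`` is the standard deviation
    of the independent per-half Gaussian noise, on the scale of a
    ground truth normalised to unit RMS inside the mask interior.
    """

    box_size: int = 64
    subunit_truncations: tuple[float, ...] = DEFAULT_TRUNCATIONS
    blob_count_per_subunit: int = 400
    noise_sigma: float = 1.2
    seed: int = 0
    mask_radius: float | None = None  # voxels; default 0.45 * box_size

    def __post_init__(self) -> None:
        if self.box_size < 8:
            raise ValueError("box_size must be >= 8")
        for f in self.subunit_truncations:
            if not 0.0 < f <= 0.5:
                raise ValueError(
                    f"truncation frequencies must lie in (0, 0.5], got {f}"
                )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mask_radius is None:
            self.mask_radius = 0.45 * self.box_size

    @property
    def n_subunits(self) -> int:
        return len(self.subunit_truncations)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        d["subunit_truncations"] = tuple(d["subunit_truncations"])
        return cls(**d)


def _cylindrical_coords(box: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.indices((box,) * 3, dtype=np.float64)
    centre = (box - 1) / 2.0
    x, y, z = idx[0] - centre, idx[1] - centre, idx[2] - centre
    rho = np.sqrt(x**2 + y**2)
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    return rho, theta, z


def _cos_edge(signed_dist: np.ndarray) -> np.ndarray:
    """Cosine ramp: 0 where signed_dist <= 0, 1 where >= the edge width."""
    t = np.clip(signed_dist / _SOFT_EDGE, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def _sector_mask(
    spec: PhantomSpec, sector: int, rho, theta, z
) -> MaskVolume:
    """Soft mask isolating the scatterer-filled part of one ring segment.

    The mask is an angular wedge intersected with the radial annulus
    and z slab the scatterers occupy, all with 3-voxel cosine edges.
    The angular edge reaches zero 2 voxels of arc inside the sector
    boundary, so adjacent masks never overlap and their interiors avoid
    density that leaked across the boundary during low-passing.
    """
    n = spec.n_subunits
    width = 2 * np.pi / n
    centre_angle = (sector + 0.5) * width
    d_theta = np.abs(np.mod(theta - centre_angle + np.pi, 2 * np.pi) - np.pi)
    # arc-length distance inside the (eroded) sector boundary; the erosion
    # (4 voxels at the default box, scaled with box size) keeps the
    # interior clear of density the neighbouring sector's truncation
    # kernel smeared across the boundary
    erosion = 4.0 * spec.box_size / 64.0
    arc_margin = (width / 2 - d_theta) * np.maximum(rho, 1e-9) - erosion
    ang = _cos_edge(arc_margin)

    ring = 0.30 * spec.box_size
    radial = _cos_edge(rho - 0.65 * ring) * _cos_edge(1.25 * ring - rho)
    slab = _cos_edge(0.12 * spec.box_size - np.abs(z))

    return MaskVolume(data=ang * radial * slab)


#: Width of the Gaussian scatterers (voxels). Near-point scatterers keep
#: each sector's spectrum nearly flat up to its truncation cutoff, so the
#: local SNR is maintained with resolution, as the study design requires.
_BLOB_SIGMA = 0.5


def ring_mask(spec: PhantomSpec) -> MaskVolume:
    """Soft mask hugging the whole scatterer-filled ring.

    This is the phantom's refinement mask: like a real particle mask it
    follows the molecule instead of enclosing a large empty sphere, so
    mask-interior statistics are dominated by structure, not solvent.
    """
    box = spec.box_size
    rho, _theta, z = _cylindrical_coords(box)
    ring = 0.30 * box
    radial = _cos_edge(rho - (0.55 * ring - 3.0)) * _cos_edge(
        1.35 * ring - rho
    )
    slab = _cos_edge(0.15 * box - np.abs(z))
    return MaskVolume(data=radial * slab)


def _sector_blob_field(
    spec: PhantomSpec, sector: int, rng: np.random.Generator
) -> np.ndarray:
    """Dense random Gaussian scatterers confined to one angular sector.

    Scatterer amplitudes are splatted onto the grid with trilinear
    weights and convolved with a Gaussian kernel in Fourier space, so a
    sector can be packed densely enough that a typical interior voxel
    carries structure rather than background.
    """
    box = spec.box_size
    n_blobs = spec.blob_count_per_subunit
    width = 2 * np.pi / spec.n_subunits
    ring_radius = 0.30 * box
    # angular margin keeps scatterer centres an arc-length ~5 voxels off
    # the sector boundaries
    margin = min(5.0 / ring_radius, 0.3 * width)
    centre = (box - 1) / 2.0

    angle = sector * width + margin + rng.random(n_blobs) * (width - 2 * margin)
    rho = ring_radius * (0.6 + 0.7 * rng.random(n_blobs))
    cx = centre + rho * np.cos(angle)
    cy = centre + rho * np.sin(angle)
    cz = centre + (rng.random(n_blobs) - 0.5) * 0.3 * box
    amp = 0.5 + rng.random(n_blobs)

    vol = np.zeros((box,) * 3)
    base = np.floor([cx, cy, cz]).astype(np.int64)
    frac = np.stack([cx, cy, cz]) - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                np.add.at(
                    vol,
                    (base[0] + dx, base[1] + dy, base[2] + dz),
                    amp * w,
                )
    # Gaussian convolution in Fourier space (blobs sit far from the box
    # edge, so periodic wrap-around is negligible)
    r = sm.radius_grid(box)
    kernel = np.exp(-2.0 * np.pi**2 * (_BLOB_SIGMA * r / box) ** 2)
    return sm.inverse_transform(sm.forward_transform(vol) * kernel)


def sector_fields(spec: PhantomSpec) -> list[np.ndarray]:
    """The isolated, truncated density field of each sector (pre-sum).

    Each field is the sector's scatterer density, whitened to a flat
    per-coefficient amplitude and Butterworth low-passed to the
    sector's truncation frequency. Whitening keeps the sector's
    signal-to-noise against the white map noise constant with
    resolution up to its cutoff, mirroring a synthetic benchmark whose
    SNR is explicitly maintained across resolution.
    """
    box = spec.box_size
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subunits)
    shell_map = sm.shell_index_map(box)
    counts = np.maximum(np.bincount(shell_map.ravel()), 1)
    fields = []
    for s, trunc in enumerate(spec.subunit_truncations):
        blobs = _sector_blob_field(spec, s, np.random.default_rng(streams[s]))
        f = sm.forward_transform(blobs)
        mean_amp = np.bincount(shell_map.ravel(), weights=np.abs(f).ravel())
        mean_amp = mean_amp / counts
        profile = np.where(mean_amp > 0, mean_amp, 1.0)
        f = f / profile[shell_map]
        fields.append(
            sm.inverse_transform(f * sm.lowpass_weights(box, trunc * box))
        )
    return fields


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[DensityVolume, list[MaskVolume]]:
    """Build the stepped-resolution ground truth and its sector masks.

    The truncated sector fields (see :func:`sector_fields`) are summed;
    sectors are deliberately not rescaled to equal power — they
    represent the same kind of structure truncated at different
    resolutions, so a sector truncated higher legitimately retains
    more power. The total is normalised to unit RMS inside the ring
    mask interior.
    """
    box = spec.box_size
    rho, theta, z = _cylindrical_coords(box)
    masks = [
        _sector_mask(spec, s, rho, theta, z) for s in range(spec.n_subunits)
    ]
    total = np.zeros((box,) * 3)
    for field in sector_fields(spec):
        total += field
    rms = np.sqrt(np.mean(total[ring_mask(spec).interior] ** 2))
    if rms > 0:
        total = total / rms
    return DensityVolume(total), masks


def make_half_pair(
    ground_truth: DensityVolume,
    noise_sigma: float,
    seed: int,
    mask: MaskVolume,
) -> HalfMapPair:
    """Add two statistically independent Gaussian noise fields.

    The two halves draw from distinct child streams of the one seed, so
    their noise realisations are independent but jointly reproducible.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    children = np.random.SeedSequence(seed).spawn(2)
    halves = []
    for child in children:
        rng = np.random.default_rng(child)
        noise = rng.normal(0.0, noise_sigma, ground_truth.data.shape)
        halves.append(
            DensityVolume(
                ground_truth.data + noise,
                ground_truth.voxel_size,
                ground_truth.origin,
            )
        )
    return HalfMapPair(half1=halves[0], half2=halves[1], mask=mask)


def plant_correlated_artefact(
    pair: HalfMapPair,
    region_mask: MaskVolume,
    band: tuple[float, float],
    amplitude: float,
    seed: int,
) -> HalfMapPair:
    """Add one identical band-limited noise field to both halves of a region.

    This is a stand-in for over-fitted density: noise that iterative
    alignment has stabilised identically into both half-sets, so it
    correlates like signal. ``band`` is (low, high) in cycles/voxel and
    should sit above the region's true truncation frequency;
    ``amplitude`` is the RMS of the planted field inside the region
    interior. Deterministic per seed.
    """
    box = pair.box_size
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError(f"need 0 <= low < high in band, got {band}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    white = rng.normal(0.0, 1.0, (box,) * 3)
    f = sm.forward_transform(white)
    banded = sm.inverse_transform(
        f * sm.bandpass_weights(box, lo * box, hi * box)
    )
    banded *= region_mask.data
    interior = region_mask.interior
    rms = np.sqrt(np.mean(banded[interior] ** 2))
    if rms > 0 and amplitude > 0:
        banded *= amplitude / rms
    else:
        banded[:] = 0.0
    return HalfMapPair(
        half1=DensityVolume(
            pair.half1.data + banded, pair.half1.voxel_size, pair.half1.origin
        ),
        half2=DensityVolume(
            pair.half2.data + banded, pair.half2.voxel_size, pair.half2.origin
        ),
        mask=pair.mask,
    )


def masked_region_fsc(halves, region_mask: MaskVolume) -> np.ndarray:
    """Per-shell FSC restricted to one region of a pair of volumes.

    ``halves`` may be a :class:`HalfMapPair`, a filter result with
    ``filtered_half1/2`` attributes, or a 2-tuple of volumes.
    """
    if isinstance(halves, HalfMapPair):
        v1, v2 = halves.half1, halves.half2
    elif hasattr(halves, "filtered_half1"):
        v1, v2 = halves.filtered_half1, halves.filtered_half2
    else:
        v1, v2 = halves
    return sm.compute_fsc(v1, v2, region_mask)
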