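"""Fourier-domain primitives: transforms, shell indexing, FSC and filters.

All spatial frequencies are expressed in reciprocal-voxel index units
(the radius ``r = f * box_size`` where ``f`` is in cycles/voxel), so the
Nyquist limit sits at index ``box_size // 2``. Resolution shells are one
index wide, half-open ``[k, k+1)``, which makes the shell width ``h - l``
appearing in the normalisation a constant 1 and matches the usual
convention for FSC curves.

Transforms are unnormalised forward / 1/N-normalised inverse; every
ratio the filter consumes (FSC, power fractions, spectrum ratios) is
invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft

from .volume_io import DensityVolume, MaskVolume

__all__ = [
    "ShellProfile",
    "forward_transform",
    "inverse_transform",
    "nyquist_shell",
    "radius_grid",
    "shell_index_map",
    "shell_coefficient_counts",
    "compute_fsc",
    "fsc_to_cref",
    "amplitude_spectrum",
    "lowpass_weights",
    "bandpass_weights",
]

#: Butterworth order parameter: the response is 1/(1 + (r/h)^(2*ORDER)).
_BUTTERWORTH_EXPONENT = 16


@dataclass
class ShellProfile:
    """Per-shell global statistics shared between the two half-sets.

    These scalars — and nothing voxel-wise — are the only information
    that crosses between the halves during filtering.
    """

    shell_index: int
    low_edge: float
    high_edge: float
    n_coeff: int
    fsc: float = 0.0
    cref: float = 0.0
    s_in1: float = 0.0  # mean Fourier amplitude, masked half 1
    s_in2: float = 0.0  # mean Fourier amplitude, masked half 2
    t_power: float = 0.0
    n_power: float = 0.0
    p_signal: float = 0.0
    p_noise: float = 0.0
    empty: bool = False

    @property
    def width(self) -> float:
        return self.high_edge - self.low_edge


def forward_transform(data: np.ndarray) -> np.ndarray:
    """Unnormalised forward 3-D FFT (full complex layout)."""
    return scipy.fft.fftn(data)


def inverse_transform(coeffs: np.ndarray) -> np.ndarray:
    """1/N-normalised inverse FFT; returns the real part."""
    return scipy.fft.ifftn(coeffs).real


def nyquist_shell(box_size: int) -> int:
    """Index of the highest shell fully inside the Nyquist sphere."""
    return box_size // 2


@lru_cache(maxsize=8)
def radius_grid(box_size: int) -> np.ndarray:
    """Spatial-frequency radius of every coefficient, in index units."""
    freqs = np.fft.fftfreq(box_size) * box_size
    kx, ky, kz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    r = np.sqrt(kx**2 + ky**2 + kz**2)
    r.flags.writeable = False
    return r


@lru_cache(maxsize=8)
def shell_index_map(box_size: int) -> np.ndarray:
    """Shell assignment floor(r) for every Fourier coefficient.

    Shell k covers radii [k, k+1); indices above the Nyquist shell are
    produced for corner coefficients and are excluded from all shell
    statistics (but still receive filter weights).
    """
    if box_size < 8:
        raise ValueError(f"box_size must be >= 8, got {box_size}")
    s = np.floor(radius_grid(box_size)).astype(np.int64)
    s.flags.writeable = False
    return s


@lru_cache(maxsize=8)
def shell_coefficient_counts(box_size: int) -> np.ndarray:
    """Number of coefficients in each shell 0..nyquist (full FFT layout)."""
    nyq = nyquist_shell(box_size)
    counts = np.bincount(
        shell_index_map(box_size).ravel(), minlength=nyq + 1
    )[: nyq + 1]
    counts.flags.writeable = False
    return counts


def _shell_sums(values: np.ndarray, box_size: int) -> np.ndarray:
    nyq = nyquist_shell(box_size)
    return np.bincount(
        shell_index_map(box_size).ravel(),
        weights=values.ravel(),
        minlength=nyq + 1,
    )[: nyq + 1]


def _masked_fft(vol: DensityVolume, mask: MaskVolume | None) -> np.ndarray:
    data = vol.data if mask is None else vol.data * mask.data
    return forward_transform(data)


def compute_fsc(
    v1: DensityVolume, v2: DensityVolume, mask: MaskVolume | None = None
) -> np.ndarray:
    """Fourier shell correlation of two (optionally masked) volumes.

    Per shell: Re(Σ F1 F2*) / sqrt(Σ|F1|² · Σ|F2|²), clamped to [-1, 1].
    Shells where either map has zero power get FSC 0.
    """
    box = v1.box_size
    f1 = _masked_fft(v1, mask)
    f2 = _masked_fft(v2, mask)
    num = _shell_sums((f1 * np.conj(f2)).real, box)
    p1 = _shell_sums(np.abs(f1) ** 2, box)
    p2 = _shell_sums(np.abs(f2) ** 2, box)
    denom = np.sqrt(p1 * p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = np.where(denom > 0, num / denom, 0.0)
    return np.clip(fsc, -1.0, 1.0)


def fsc_to_cref(fsc):
    """Map a half-map FSC to C_ref, the figure of merit against the truth.

    C_ref = sqrt(2 FSC / (1 + FSC)) for FSC > 0, else 0 — so that
    FSC = 0.143 gives C_ref = 0.5, the standard resolution criterion.
    Accepts scalars or arrays.
    """
    fsc_arr = np.clip(np.asarray(fsc, dtype=np.float64), -1.0, 1.0)
    pos = fsc_arr > 0
    out = np.zeros_like(fsc_arr)
    out[pos] = np.sqrt(2.0 * fsc_arr[pos] / (1.0 + fsc_arr[pos]))
    if np.isscalar(fsc) or np.ndim(fsc) == 0:
        return float(out)
    return out


def amplitude_spectrum(
    v: DensityVolume, mask: MaskVolume | None = None
) -> np.ndarray:
    """Mean Fourier amplitude per shell of the (masked) volume.

    Per shell: (1/n) Σ |F_i| over the n coefficients in the shell.
    Empty shells give 0.
    """
    box = v.box_size
    f = _masked_fft(v, mask)
    sums = _shell_sums(np.abs(f), box)
    counts = shell_coefficient_counts(box)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def lowpass_weights(box_size: int, h: float) -> np.ndarray:
    """Eighth-order Butterworth low-pass: weight 1/(1 + (r/h)^16).

    ``h`` is the cutoff in index units (weight 0.5 at r = h, 1 at DC).
    """
    if not h > 0:
        raise ValueError(f"cutoff h must be positive, got {h}")
    r = radius_grid(box_size)
    return 1.0 / (1.0 + (r / h) ** _BUTTERWORTH_EXPONENT)


def bandpass_weights(box_size: int, l: float, h: float) -> np.ndarray:
    """Eighth-order Butterworth band-pass as the difference of low-passes.

    weight(r) = 1/(1+(r/h)^16) − 1/(1+(r/l)^16); ``l == 0`` omits the
    low-side term, giving a pure low-pass. Computed literally as the
    difference of :func:`lowpass_weights` responses so a contiguous bank
    telescopes exactly. Slightly negative values in the far stop-band
    are a property of the printed response and are accepted.
    """
    if l < 0 or l >= h:
        raise ValueError(f"need 0 <= l < h, got l={l}, h={h}")
    if l == 0:
        return lowpass_weights(box_size, h)
    return lowpass_weights(box_size, h) - lowpass_weights(box_size, l)


def fsc_table(
    fsc: np.ndarray, box_size: int, voxel_size: float
) -> str:
    """Plain-text FSC table: shell, cycles/voxel, resolution (Å), FSC, C_ref."""
    lines = ["shell\tcyc_per_voxel\tresolution_A\tfsc\tcref"]
    for k, value in enumerate(fsc):
        f_cv = k / box_size
        res = (voxel_size / f_cv) if f_cv > 0 else np.inf
        lines.append(
            f"{k}\t{f_cv:.5f}\t{res:.3f}\t{value:.4f}\t{fsc_to_cref(value):.4f}"
        )
    return "\n".join(lines) + "\n"
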