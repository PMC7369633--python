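"""Global per-shell power decomposition and extreme-value noise bounds.

Everything in this module is a global scalar computed inside the mask
interior. These scalars are the only information the filter shares
between the two half-sets: the half-difference power, its observed
maximum, and the Gaussian extreme-value bound RMSD·sqrt(2 ln n). The
voxel data of one half never reaches the filtering of the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseBound",
    "shell_power_stats",
    "observed_noise_max",
    "expected_noise_bound",
    "select_noise_bound",
    "measure_noise_bound",
]


@dataclass(frozen=True)
class NoiseBound:
    """The two noise-maximum estimates for one low-pass cutoff.

    ``used`` is the larger of the observed maximum of the halved voxel
    differences and the Gaussian expected bound. The expected bound is
    the better estimate for near-normal noise; the observed maximum is
    the fall-back when symmetry averaging has made the noise non-normal.
    """

    observed: float
    expected: float
    n_voxels: int
    rmsd_halfdiff: float

    def __post_init__(self) -> None:
        for name in ("observed", "expected", "rmsd_halfdiff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def used(self) -> float:
        return max(self.observed, self.expected)


def _interior(mask) -> np.ndarray:
    interior = mask.interior
    if not interior.any():
        raise ValueError("mask has an empty interior")
    return interior


def shell_power_stats(b1, b2, mask) -> tuple[float, float, float, float]:
    """Signal/noise power split of one isolated resolution band.

    Over mask-interior voxels: T = Σ((v1+v2)/2)² is the power of the
    combined band, N = Σ((v1−v2)/2)² the power of the noise. Returns
    ``(t_power, n_power, p_signal, p_noise)`` with P_N = N/T and
    P_S = 1 − P_N clamped to [0, 1]. T == 0 flags an empty shell
    (p_signal 0), which terminates processing downstream.
    """
    interior = _interior(mask)
    v1 = b1.data[interior]
    v2 = b2.data[interior]
    t_power = float(np.sum(((v1 + v2) / 2.0) ** 2))
    n_power = float(np.sum(((v1 - v2) / 2.0) ** 2))
    if t_power == 0.0:
        return 0.0, n_power, 0.0, 1.0
    p_noise = n_power / t_power
    p_signal = float(np.clip(1.0 - p_noise, 0.0, 1.0))
    return t_power, n_power, p_signal, min(p_noise, 1.0)


def observed_noise_max(v1, v2, mask) -> float:
    """Largest halved voxel difference inside the mask: max |v1 − v2| / 2."""
    interior = _interior(mask)
    return float(np.max(np.abs(v1.data[interior] - v2.data[interior])) / 2.0)


def expected_noise_bound(v1, v2, mask) -> float:
    """Gaussian upper bound on the maximum noise excursion.

    RMSD of the halved voxel differences over the n mask-interior
    voxels, times sqrt(2 ln n) — the standard extreme-value bound for
    the maximum of n centred Gaussians.
    """
    interior = _interior(mask)
    n = int(interior.sum())
    if n < 2:
        raise ValueError(f"need at least 2 mask-interior voxels, got {n}")
    half_diff = (v1.data[interior] - v2.data[interior]) / 2.0
    rmsd = float(np.sqrt(np.mean(half_diff**2)))
    return rmsd * float(np.sqrt(2.0 * np.log(n)))


def select_noise_bound(
    observed: float,
    expected: float,
    n_voxels: int = 0,
    rmsd_halfdiff: float = 0.0,
) -> NoiseBound:
    """Record both bounds; whichever is greater is the one used."""
    return NoiseBound(
        observed=float(observed),
        expected=float(expected),
        n_voxels=int(n_voxels),
        rmsd_halfdiff=float(rmsd_halfdiff),
    )


def measure_noise_bound(v1, v2, mask) -> NoiseBound:
    """Compute both bounds for a low-passed pair and select the larger."""
    interior = _interior(mask)
    n = int(interior.sum())
    half_diff = (v1.data[interior] - v2.data[interior]) / 2.0
    observed = float(np.max(np.abs(half_diff)))
    rmsd = float(np.sqrt(np.mean(half_diff**2)))
    expected = rmsd * float(np.sqrt(2.0 * np.log(n))) if n >= 2 else 0.0
    return select_noise_bound(observed, expected, n, rmsd)
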