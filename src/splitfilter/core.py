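"""The two-pass local SNR filter for split half-map pairs.

Pass one normalises each half map shell-by-shell so that signal can be
compared against noise independently of resolution; pass two assigns
each voxel its value at the highest resolution at which its magnitude
exceeds a global extreme-value bound on the noise, then restores the
original grey-scale and tapers the spectrum by C_ref.

Independence between the half-sets is structural: after the shared
schedule and noise bounds (all global per-shell scalars) are computed,
each half is filtered by :func:`filter_half`, whose arguments contain no
voxel data from the other half. Sharing only these statistics keeps the
leakage between the sides no greater than that of conventional global
FSC weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import shell_math as sm
from .noise_stats import NoiseBound, measure_noise_bound, shell_power_stats
from .volume_io import DensityVolume, HalfMapPair, MaskVolume

__all__ = [
    "CutoffSchedule",
    "FilterResult",
    "build_schedule",
    "normalize_pass",
    "normalize_half",
    "normalization_transfer",
    "compute_noise_bounds",
    "progressive_assign",
    "restore_greyscale",
    "apply_final_spectrum",
    "filter_half",
    "run_filter",
]

FSC_THRESHOLD = 0.143
P_SIGNAL_THRESHOLD = 0.05


@dataclass
class CutoffSchedule:
    """The ordered shells actually processed, after the termination rules.

    Shells run contiguously from 0 to ``terminated_at``. Walking upward
    in frequency, incorporation stops before the first shell whose
    masked FSC falls below the FSC threshold or whose signal fraction
    P_S falls below the signal threshold, whichever comes first; shell 0
    (the DC shell) is always retained. All fields are global scalars.
    """

    shells: list[sm.ShellProfile]
    terminated_at: int
    termination_reason: str  # fsc_below_threshold | p_signal_below_threshold | nyquist
    n_interior: int
    box_size: int
    voxel_size: float

    def __post_init__(self) -> None:
        indices = [s.shell_index for s in self.shells]
        if indices != list(range(len(indices))):
            raise ValueError("schedule shells must be contiguous from shell 0")
        if self.terminated_at != indices[-1]:
            raise ValueError("terminated_at must equal the last shell index")

    @property
    def active_shells(self) -> list[sm.ShellProfile]:
        """Shells that carry power (empty shells are dropped from pass two)."""
        return [s for s in self.shells if not s.empty]

    def table(self) -> str:
        """Tab-separated diagnostic table of every shared global scalar."""
        lines = [
            "shell\tlow\thigh\tfsc\tcref\tp_signal\tp_noise\tt_power\ts_in1\ts_in2"
        ]
        for s in self.shells:
            lines.append(
                f"{s.shell_index}\t{s.low_edge:g}\t{s.high_edge:g}\t{s.fsc:.4f}"
                f"\t{s.cref:.4f}\t{s.p_signal:.4f}\t{s.p_noise:.4f}"
                f"\t{s.t_power:.6g}\t{s.s_in1:.6g}\t{s.s_in2:.6g}"
            )
        lines.append(
            f"# terminated_at={self.terminated_at}"
            f" reason={self.termination_reason} n_interior={self.n_interior}"
        )
        return "\n".join(lines) + "\n"


@dataclass
class FilterResult:
    """Filtered half pair plus the diagnostics of how it was produced."""

    filtered_half1: DensityVolume
    filtered_half2: DensityVolume
    schedule: CutoffSchedule
    bounds: dict[int, NoiseBound]
    assigned_resolution1: np.ndarray = field(repr=False)
    assigned_resolution2: np.ndarray = field(repr=False)


def _band_volume(coeffs: np.ndarray, box: int, l: float, h: float) -> np.ndarray:
    return sm.inverse_transform(coeffs * sm.bandpass_weights(box, l, h))


def build_schedule(
    pair: HalfMapPair,
    fsc_threshold: float = FSC_THRESHOLD,
    p_signal_threshold: float = P_SIGNAL_THRESHOLD,
) -> CutoffSchedule:
    """First-pass analysis: per-shell FSC, C_ref, spectra and termination.

    The masked FSC and amplitude spectra are computed once; then shells
    are walked from low to high frequency, band-passing the unmasked
    halves to obtain the T/N power split inside the mask. The walk stops
    before the first shell with FSC below ``fsc_threshold`` or P_S below
    ``p_signal_threshold``. Shell 0 is always included; if it carries no
    power at all the input is empty or noise-only and an error is raised.
    """
    box = pair.box_size
    nyq = sm.nyquist_shell(box)
    mask = pair.mask
    n_interior = int(mask.interior.sum())

    fsc = sm.compute_fsc(pair.half1, pair.half2, mask)
    cref = sm.fsc_to_cref(fsc)
    s_in1 = sm.amplitude_spectrum(pair.half1, mask)
    s_in2 = sm.amplitude_spectrum(pair.half2, mask)
    counts = sm.shell_coefficient_counts(box)

    f1 = sm.forward_transform(pair.half1.data)
    f2 = sm.forward_transform(pair.half2.data)

    shells: list[sm.ShellProfile] = []
    reason = "nyquist"
    for k in range(nyq + 1):
        if k > 0 and fsc[k] < fsc_threshold:
            reason = "fsc_below_threshold"
            break
        b1 = _band_volume(f1, box, float(k), float(k + 1))
        b2 = _band_volume(f2, box, float(k), float(k + 1))
        t, n, p_s, p_n = shell_power_stats(
            DensityVolume(b1, pair.voxel_size),
            DensityVolume(b2, pair.voxel_size),
            mask,
        )
        if k == 0 and t == 0.0:
            raise ValueError(
                "shell 0 carries no power inside the mask; "
                "input maps are empty or noise-only"
            )
        if k > 0 and p_s < p_signal_threshold:
            reason = "p_signal_below_threshold"
            break
        shells.append(
            sm.ShellProfile(
                shell_index=k,
                low_edge=float(k),
                high_edge=float(k + 1),
                n_coeff=int(counts[k]),
                fsc=float(fsc[k]),
                cref=float(cref[k]),
                s_in1=float(s_in1[k]),
                s_in2=float(s_in2[k]),
                t_power=t,
                n_power=n,
                p_signal=p_s,
                p_noise=p_n,
                empty=(t == 0.0),
            )
        )
    return CutoffSchedule(
        shells=shells,
        terminated_at=shells[-1].shell_index,
        termination_reason=reason,
        n_interior=n_interior,
        box_size=box,
        voxel_size=pair.voxel_size,
    )


def normalization_transfer(schedule: CutoffSchedule) -> np.ndarray:
    """Per-coefficient transfer g(r) of the shell-normalisation pass.

    g(r) = Σ_k [(h−l)/sqrt(T_k/n)] · W_k(r) over the non-empty scheduled
    shells, with W_k the Butterworth band-pass of shell k. Normalising a
    map is multiplication of its transform by g; restoring the
    grey-scale is division by g, so the pair inverts exactly (summing
    reciprocal-scaled bands would not: neighbouring Butterworth bands
    overlap, and their cross terms break the inversion wherever
    adjacent shells carry very different power).
    """
    box = schedule.box_size
    g = np.zeros((box,) * 3)
    for s in schedule.active_shells:
        scale = s.width / np.sqrt(s.t_power / schedule.n_interior)
        g += scale * sm.bandpass_weights(box, s.low_edge, s.high_edge)
    return g


def normalize_half(
    half: DensityVolume, schedule: CutoffSchedule
) -> DensityVolume:
    """Shell-normalise one unmasked half map using the shared schedule.

    Each scheduled band is isolated with the Butterworth band-pass and
    scaled by (h−l)/sqrt(T/n), flattening the power over resolution so
    voxel values become comparable with the noise bounds. Empty shells
    contribute zero.
    """
    f = sm.forward_transform(half.data)
    out = sm.inverse_transform(f * normalization_transfer(schedule))
    return DensityVolume(out, half.voxel_size, half.origin)


def normalize_pass(
    pair: HalfMapPair, schedule: CutoffSchedule
) -> tuple[DensityVolume, DensityVolume]:
    """Normalise both halves (see :func:`normalize_half`)."""
    return (
        normalize_half(pair.half1, schedule),
        normalize_half(pair.half2, schedule),
    )


def compute_noise_bounds(
    norm1: DensityVolume,
    norm2: DensityVolume,
    mask: MaskVolume,
    schedule: CutoffSchedule,
) -> dict[int, NoiseBound]:
    """One shared noise bound per low-pass cutoff of the schedule.

    At each cutoff both normalised halves are low-passed and the halved
    voxel difference inside the mask yields the observed maximum and the
    Gaussian sqrt(2 ln n) bound; the larger is used. The result is a set
    of global scalars — the only half-to-half information in pass two.
    """
    box = norm1.box_size
    f1 = sm.forward_transform(norm1.data)
    f2 = sm.forward_transform(norm2.data)
    bounds: dict[int, NoiseBound] = {}
    for s in schedule.active_shells:
        w = sm.lowpass_weights(box, s.high_edge)
        lp1 = DensityVolume(sm.inverse_transform(f1 * w), norm1.voxel_size)
        lp2 = DensityVolume(sm.inverse_transform(f2 * w), norm2.voxel_size)
        bounds[s.shell_index] = measure_noise_bound(lp1, lp2, mask)
    return bounds


def progressive_assign(
    normalized_half: DensityVolume,
    schedule: CutoffSchedule,
    bounds: dict[int, NoiseBound],
) -> tuple[DensityVolume, np.ndarray]:
    """Assign each voxel its value at the highest resolution above noise.

    Walking cutoffs from highest to lowest, the normalised half is
    low-pass filtered and any still-unassigned voxel whose absolute
    value exceeds that cutoff's noise bound is frozen at that value
    (density may be legitimately negative after band limiting, hence the
    absolute value). Voxels never exceeding any bound receive their
    lowest-cutoff value unconditionally, so low-frequency signal always
    survives. Returns the assigned volume and the per-voxel shell index
    at which each voxel was frozen.
    """
    box = normalized_half.box_size
    f = sm.forward_transform(normalized_half.data)
    shells_desc = sorted(
        schedule.active_shells, key=lambda s: s.shell_index, reverse=True
    )
    assigned = np.zeros_like(normalized_half.data)
    assigned_shell = np.full(normalized_half.data.shape, -1, dtype=np.int64)
    unassigned = np.ones(normalized_half.data.shape, dtype=bool)
    lp = None
    lowest = shells_desc[-1]
    for s in shells_desc:
        lp = sm.inverse_transform(f * sm.lowpass_weights(box, s.high_edge))
        newly = unassigned & (np.abs(lp) > bounds[s.shell_index].used)
        assigned[newly] = lp[newly]
        assigned_shell[newly] = s.shell_index
        unassigned &= ~newly
    # lp now holds the lowest-cutoff volume: the unconditional floor
    assigned[unassigned] = lp[unassigned]
    assigned_shell[unassigned] = lowest.shell_index
    return (
        DensityVolume(assigned, normalized_half.voxel_size, normalized_half.origin),
        assigned_shell,
    )


def restore_greyscale(
    assigned_half: DensityVolume, schedule: CutoffSchedule
) -> DensityVolume:
    """Invert the shell normalisation: scale shell k back by sqrt(T/n)/(h−l).

    Implemented as division by the normalisation transfer g(r), the
    exact inverse of :func:`normalize_half`. Coefficients where g is
    vanishingly small (the far stop-band beyond the schedule, which the
    final spectrum step zeroes anyway) are set to zero rather than
    amplified.
    """
    f = sm.forward_transform(assigned_half.data)
    g = normalization_transfer(schedule)
    g_min = 1e-9 * np.max(np.abs(g))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(np.abs(g) > g_min, 1.0 / g, 0.0)
    out = sm.inverse_transform(f * inv)
    return DensityVolume(out, assigned_half.voxel_size, assigned_half.origin)


def apply_final_spectrum(
    restored_half: DensityVolume,
    mask: MaskVolume,
    s_in: np.ndarray,
    cref: np.ndarray,
    terminated_at: int,
) -> DensityVolume:
    """Match the output spectrum to C_ref · S_in and zero beyond termination.

    The restored half is masked, its shell spectrum S_out measured, and
    every coefficient in shell k ≤ ``terminated_at`` multiplied by
    cref_k · s_in_k / s_out_k (0 where S_out vanishes). All shells above
    the termination shell — including corner frequencies — are zeroed,
    so the output carries exactly no energy beyond the schedule.
    """
    box = restored_half.box_size
    masked = restored_half.data * mask.data
    f = sm.forward_transform(masked)
    shell_map = sm.shell_index_map(box)
    counts = np.bincount(shell_map.ravel())
    sums = np.bincount(shell_map.ravel(), weights=np.abs(f).ravel())
    with np.errstate(invalid="ignore", divide="ignore"):
        s_out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    factor = np.zeros(int(shell_map.max()) + 1)
    upto = min(terminated_at, len(s_in) - 1, len(s_out) - 1)
    for k in range(upto + 1):
        if s_out[k] > 0:
            factor[k] = cref[k] * s_in[k] / s_out[k]
    out = sm.inverse_transform(f * factor[shell_map])
    return DensityVolume(out, restored_half.voxel_size, restored_half.origin)


def filter_half(
    half: DensityVolume,
    mask: MaskVolume,
    schedule: CutoffSchedule,
    bounds: dict[int, NoiseBound],
    s_in: np.ndarray,
    cref: np.ndarray,
    normalized: DensityVolume | None = None,
) -> tuple[DensityVolume, np.ndarray]:
    """Complete second pass for one half map.

    Everything the other half contributed is already baked into the
    global scalars of ``schedule``, ``bounds`` and ``cref``; this
    function never touches the other half's voxels, which is the
    package's independence guarantee in API form. ``normalized`` may be
    supplied to reuse an already-computed first pass for this half.
    """
    if normalized is None:
        normalized = normalize_half(half, schedule)
    assigned, assigned_map = progressive_assign(normalized, schedule, bounds)
    restored = restore_greyscale(assigned, schedule)
    out = apply_final_spectrum(restored, mask, s_in, cref, schedule.terminated_at)
    return out, assigned_map


def run_filter(
    pair: HalfMapPair,
    fsc_threshold: float = FSC_THRESHOLD,
    p_signal_threshold: float = P_SIGNAL_THRESHOLD,
    taper: bool = True,
) -> FilterResult:
    """Filter a half-map pair end to end.

    Builds the shared schedule, normalises both halves, derives the
    per-cutoff noise bounds, then filters each half independently. With
    ``taper=False`` the final C_ref taper is replaced by plain spectrum
    matching (cref treated as 1 in every scheduled shell).
    """
    schedule = build_schedule(pair, fsc_threshold, p_signal_threshold)
    norm1, norm2 = normalize_pass(pair, schedule)
    bounds = compute_noise_bounds(norm1, norm2, pair.mask, schedule)

    nyq = sm.nyquist_shell(pair.box_size)
    s_in1 = np.zeros(nyq + 1)
    s_in2 = np.zeros(nyq + 1)
    cref = np.zeros(nyq + 1)
    for s in schedule.shells:
        s_in1[s.shell_index] = s.s_in1
        s_in2[s.shell_index] = s.s_in2
        cref[s.shell_index] = s.cref if taper else 1.0

    out1, amap1 = filter_half(
        pair.half1, pair.mask, schedule, bounds, s_in1, cref, normalized=norm1
    )
    out2, amap2 = filter_half(
        pair.half2, pair.mask, schedule, bounds, s_in2, cref, normalized=norm2
    )
    return FilterResult(
        filtered_half1=out1,
        filtered_half2=out2,
        schedule=schedule,
        bounds=bounds,
        assigned_resolution1=amap1,
        assigned_resolution2=amap2,
    )
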