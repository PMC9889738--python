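"""The fCOAT algorithm: frequency-multiplexed binary-phase wavefront correction.

Every active SLM segment is tagged with its own integer dither frequency and
toggled between its base phase and base+pi as a square wave.  A single
detector behind a pinhole at the target records the interference of all
segments with a static reference field; one DFT of that intensity series
separates the segments again, and the sign of each segment's Fourier
coefficient (relative to the dither waveform's own phase) says whether the
segment currently interferes constructively or destructively with the
reference -- exactly the bit a binary SLM needs.

To keep the reference field stationary the segments are split into two
halves: while the first half is dithered the second half sits still and acts
as the reference; the corrected first half then serves as (a much brighter)
reference for the second half.  With H segments per half, frequencies occupy
the integer DFT bins [T/4, T/2) of a T = 4*H sample record -- the band's
lowest frequency is half its highest, which avoids the poorly sampled
low-frequency bins.  One full correction therefore costs 2*T = 4*M displayed
patterns; for a 32x32 grid with the inscribed-circle rule (M = 812) that is
3248 measurements.

Known imperfection, accepted by design: square-wave dithers carry odd
harmonics, and the aliased third harmonic of bins >= 5T/12 lands back inside
the band at 1/3 amplitude, as do pairwise intermodulation products.  The
hardware this emulates has the same crosstalk; its net cost is bounded in the
test suite by comparison against a greedy coordinate-flip oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward_optics import (
    DetectionAperture,
    NoiseModel,
    OpticalConfig,
    ResponseBasis,
    SegmentLayout,
    precompute_segment_responses,
    validate_binary_phases,
)
from .scatter_media import TransmissionMedium, evolve_medium

__all__ = [
    "DitherPlan",
    "DemodResult",
    "FcoatResult",
    "plan_dither",
    "square_wave",
    "build_pattern_sequence",
    "demodulate",
    "binarize_phase",
    "run_fcoat",
    "run_greedy_oracle",
    "run_exhaustive_oracle",
]


@dataclass(frozen=True)
class DitherPlan:
    """Half-partition and per-segment frequency assignment.

    ``halves[0]`` / ``halves[1]`` hold active-segment indices (sizes differ by
    at most one); ``bins[h][j]`` is the integer DFT frequency of segment
    ``halves[h][j]`` within its half's T-sample record.
    """

    halves: tuple[np.ndarray, np.ndarray]
    bins: tuple[np.ndarray, np.ndarray]
    samples_per_half: int  # T
    scheme: str = "checkerboard"
    seed: int = 0

    @property
    def total_patterns(self) -> int:
        return 2 * self.samples_per_half


@dataclass
class DemodResult:
    """Per-segment demodulation output for one half."""

    coeffs: np.ndarray       # complex DFT coefficient c_i at the segment's bin
    ref_phases: np.ndarray   # dither waveform's own DFT phase psi_i
    phases: np.ndarray       # extracted phase in [0, 2pi)
    bits: np.ndarray         # binary decision in {0, pi}


@dataclass
class FcoatResult:
    mask: np.ndarray                     # final binary correction, (M,) in {0, pi}
    intensity_series: list[np.ndarray]   # detector record per half (per iteration)
    intensity_before: float
    intensity_after: float
    pbr_before: float | None
    pbr_after: float | None
    n_measurements: int
    seed: int
    iterations: int
    meta: dict = field(default_factory=dict)
    image_before: np.ndarray | None = None
    image_after: np.ndarray | None = None


def plan_dither(layout: SegmentLayout, scheme: str = "checkerboard",
                seed: int = 0) -> DitherPlan:
    """Partition the active segments into two halves and assign frequencies.

    ``checkerboard`` alternates segments between halves (grid layouts use
    (row+col) parity, linear layouts index parity) so both halves form
    well-mixed reference speckles; ``random`` uses a seeded shuffle.  Each
    half's segments get the ascending integer bins [T/4, T/4 + H) with
    T = 4 * max(H1, H2).
    """
    m = layout.m_active
    if m < 2:
        raise ValueError("dither planning needs at least 2 active segments")
    if scheme == "checkerboard":
        if layout.segment_map is not None:
            parity = layout.active_rc.sum(axis=1) % 2
        else:
            parity = np.arange(m) % 2
        h1 = np.nonzero(parity == 0)[0]
        h2 = np.nonzero(parity == 1)[0]
        # rebalance if the circle mask left the parities uneven
        while len(h1) - len(h2) > 1:
            h1, h2 = h1[:-1], np.sort(np.append(h2, h1[-1]))
        while len(h2) - len(h1) > 1:
            h2, h1 = h2[:-1], np.sort(np.append(h1, h2[-1]))
    elif scheme == "random":
        perm = np.random.default_rng(seed).permutation(m)
        h1, h2 = np.sort(perm[: (m + 1) // 2]), np.sort(perm[(m + 1) // 2:])
    else:
        raise ValueError(f"unknown partition scheme {scheme!r}")

    t = 4 * max(len(h1), len(h2))
    bins = tuple(np.arange(t // 4, t // 4 + len(h)) for h in (h1, h2))
    return DitherPlan(halves=(h1, h2), bins=bins, samples_per_half=t,
                      scheme=scheme, seed=seed)


def square_wave(k: int, t_samples: int) -> np.ndarray:
    """+/-1 square wave sgn(cos(2 pi k t / T)), ties -> +1, t = 0..T-1."""
    t = np.arange(t_samples)
    return np.where(np.cos(2 * np.pi * k * t / t_samples) >= 0, 1.0, -1.0)


def _sign_matrix(plan: DitherPlan, half: int) -> np.ndarray:
    """(T, H) matrix of dither signs for the modulated segments of a half."""
    t_n = plan.samples_per_half
    ks = plan.bins[half]
    t = np.arange(t_n)[:, None]
    return np.where(np.cos(2 * np.pi * t * ks[None, :] / t_n) >= 0, 1.0, -1.0)


def build_pattern_sequence(plan: DitherPlan, half: int,
                           base_mask: np.ndarray) -> np.ndarray:
    """All T binary SLM states of one half's dither, as a (T, M) phase array.

    The modulated segments toggle base <-> base+pi following their square
    wave (at t=0 every segment sits at its base value); all other segments
    hold ``base_mask`` throughout.
    """
    if half not in (0, 1):
        raise ValueError("half must be 0 (first) or 1 (second)")
    m = len(plan.halves[0]) + len(plan.halves[1])
    base = validate_binary_phases(base_mask, m)
    signs = _sign_matrix(plan, half)  # (T, H)
    seq = np.tile(base, (plan.samples_per_half, 1))
    idx = plan.halves[half]
    seq[:, idx] = np.where(signs > 0, base[idx][None, :],
                           np.mod(base[idx][None, :] + np.pi, 2 * np.pi))
    return seq


def binarize_phase(phi) -> np.ndarray | float:
    """Map a phase to the binary SLM levels: 0 on [0, pi/2) u [3pi/2, 2pi),
    pi on [pi/2, 3pi/2) (half-open intervals; input wrapped to [0, 2pi))."""
    wrapped = np.mod(np.asarray(phi, dtype=float), 2 * np.pi)
    out = np.where((wrapped >= np.pi / 2) & (wrapped < 3 * np.pi / 2), np.pi, 0.0)
    return float(out) if np.isscalar(phi) else out


def demodulate(intensity: np.ndarray, plan: DitherPlan, half: int,
               mode: str = "square") -> DemodResult:
    """Recover each modulated segment's phase from the intensity record.

    ``c_i = sum_t I(t) exp(-2 pi j k_i t / T)``; the dither waveform's own
    DFT phase ``psi_i`` at the same bin is subtracted so the extracted phase
    measures the medium, not the dither convention.  Segments with no signal
    (|c_i| ~ 0, e.g. constant input) default to the base value (bit 0).

    ``mode='square'`` matches the physical binary dither; ``mode='ramp'`` is
    the continuous phase-ramp validation mode (``exp(j 2 pi k t / T)``
    modulation, psi = 0), in which the full medium phase is recoverable
    before binarisation.
    """
    intensity = np.asarray(intensity, dtype=float)
    t_n = plan.samples_per_half
    if intensity.shape != (t_n,):
        raise ValueError(f"intensity record must have length T={t_n}")
    ks = plan.bins[half]
    t = np.arange(t_n)
    dft = np.exp(-2j * np.pi * np.outer(t, ks) / t_n)  # (T, H)
    coeffs = intensity @ dft
    if mode == "square":
        signs = _sign_matrix(plan, half)
        ref = np.sum(signs * dft, axis=0)
        psi = np.angle(ref)
    elif mode == "ramp":
        psi = np.zeros(len(ks))
    else:
        raise ValueError(f"unknown demodulation mode {mode!r}")
    no_signal = np.abs(coeffs) <= 1e-12 * (np.sum(np.abs(intensity)) + 1.0)
    phases = np.mod(np.angle(coeffs) - psi, 2 * np.pi)
    phases[no_signal] = 0.0
    bits = binarize_phase(phases)
    bits[no_signal] = 0.0
    return DemodResult(coeffs=coeffs, ref_phases=psi, phases=phases, bits=bits)


def _measure_half(basis: ResponseBasis, plan: DitherPlan, half: int,
                  base: np.ndarray, noise: NoiseModel | None) -> np.ndarray:
    """Detected intensity for each pattern of one half (static medium)."""
    signs = _sign_matrix(plan, half)  # (T, H)
    base_signs = np.where(base > np.pi / 2, -1.0, 1.0)
    full = np.tile(base_signs, (plan.samples_per_half, 1))
    idx = plan.halves[half]
    full[:, idx] = full[:, idx] * signs
    return basis.detect_series(full, noise=noise)


def _measure_half_dynamic(medium: TransmissionMedium, layout: SegmentLayout,
                          config: OpticalConfig, aperture: DetectionAperture,
                          plan: DitherPlan, half: int, base: np.ndarray,
                          noise: NoiseModel | None, pattern_dwell: float,
                          evolve_every: int) -> tuple[np.ndarray, TransmissionMedium]:
    """Same as _measure_half but the medium decorrelates under the sequence.

    The medium is refreshed in chunks of ``evolve_every`` patterns; the
    stochastic relaxation composes exactly, so chunking only coarsens the
    time discretisation, not the statistics.
    """
    t_n = plan.samples_per_half
    signs = _sign_matrix(plan, half)
    base_signs = np.where(base > np.pi / 2, -1.0, 1.0)
    idx = plan.halves[half]
    out = np.empty(t_n)
    for lo in range(0, t_n, evolve_every):
        hi = min(lo + evolve_every, t_n)
        basis = precompute_segment_responses(layout, medium, config, aperture)
        chunk = np.tile(base_signs, (hi - lo, 1))
        chunk[:, idx] = chunk[:, idx] * signs[lo:hi]
        out[lo:hi] = basis.detect_series(chunk, noise=noise)
        medium = evolve_medium(medium, (hi - lo) * pattern_dwell)
    return out, medium


def run_fcoat(
    medium: TransmissionMedium,
    layout: SegmentLayout,
    config: OpticalConfig,
    aperture: DetectionAperture,
    initial_mask: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    scheme: str = "checkerboard",
    seed: int = 0,
    iterations: int = 1,
    pattern_dwell: float = 1e-3,
    evolve_every: int = 16,
    render: bool = True,
    compute_pbr: bool = True,
) -> FcoatResult:
    """One (or more) full two-half fCOAT corrections.

    First half dithered against the second half at its base phase, decisions
    applied, then the corrected first half serves as reference while the
    second half is dithered; the combined result is the final binary mask
    (already in {0, pi}, re-binarised defensively).  A finite-tau medium
    advances its clock by ``pattern_dwell`` per displayed pattern (default
    1 ms, the net latency of a ferroelectric SLM); correction quality then
    degrades gracefully rather than failing.
    """
    m = layout.m_active
    mask = (np.zeros(m) if initial_mask is None
            else validate_binary_phases(initial_mask, m).copy())
    plan = plan_dither(layout, scheme=scheme, seed=seed)

    dynamic = np.isfinite(medium.tau)
    if dynamic and medium.tau < pattern_dwell:
        warnings.warn(
            "medium decorrelation time is shorter than one pattern dwell; "
            "the correction will be strongly degraded", RuntimeWarning,
        )

    basis = precompute_segment_responses(layout, medium, config, aperture)
    intensity_before = basis.detect(mask)
    image_before = basis.render(mask) if render else None

    series: list[np.ndarray] = []
    for _ in range(iterations):
        for half in (0, 1):
            if dynamic:
                rec, medium = _measure_half_dynamic(
                    medium, layout, config, aperture, plan, half, mask,
                    noise, pattern_dwell, evolve_every,
                )
            else:
                rec = _measure_half(basis, plan, half, mask, noise)
            series.append(rec)
            dem = demodulate(rec, plan, half, mode="square")
            idx = plan.halves[half]
            mask[idx] = np.mod(mask[idx] + dem.bits, 2 * np.pi)
    mask = binarize_phase(mask)  # defensive: keeps the device contract explicit

    if dynamic:
        basis = precompute_segment_responses(layout, medium, config, aperture)
    intensity_after = basis.detect(mask)
    image_after = basis.render(mask) if render else None

    pbr_before = pbr_after = None
    if compute_pbr and render:
        from .focus_metrics import quick_pbr  # local import avoids a cycle
        pitch = config.focal_pixel_pitch
        side = image_after.shape[0]
        target = aperture.center_px(side, pitch)
        if medium.form == "phase_screen":
            from .forward_optics import airy_fwhm_um
            excl_px = 3.0 * airy_fwhm_um(config) / pitch
        else:
            excl_px = 3.0
        pbr_before = quick_pbr(image_before, target, excl_px)
        pbr_after = quick_pbr(image_after, target, excl_px)

    return FcoatResult(
        mask=mask,
        intensity_series=series,
        intensity_before=float(intensity_before),
        intensity_after=float(intensity_after),
        pbr_before=pbr_before,
        pbr_after=pbr_after,
        n_measurements=iterations * plan.total_patterns,
        seed=seed,
        iterations=iterations,
        meta={
            "scheme": scheme,
            "half_sizes": [len(h) for h in plan.halves],
            "samples_per_half": plan.samples_per_half,
            "pattern_dwell_s": pattern_dwell,
            "medium_form": medium.form,
            "medium_seed": medium.seed,
            "medium_clock_s": float(medium.clock),
        },
        image_before=image_before,
        image_after=image_after,
    )


def run_greedy_oracle(basis: ResponseBasis, max_passes: int = 50) -> np.ndarray:
    """Sequential coordinate-flip optimiser (independent test oracle).

    Each segment in turn is set to whichever of {0, pi} maximises the
    detected intensity, repeating until a full pass makes no change.  Not
    part of the correction algorithm -- it sees the exact responses.
    """
    m = basis.m_active
    signs = np.ones(m)
    f = basis.e_static + signs @ basis.e_seg
    for _ in range(max_passes):
        changed = False
        for i in range(m):
            f_flip = f - 2.0 * signs[i] * basis.e_seg[i]
            if np.sum(np.abs(f_flip) ** 2) > np.sum(np.abs(f) ** 2):
                f = f_flip
                signs[i] = -signs[i]
                changed = True
        if not changed:
            break
    return np.where(signs > 0, 0.0, np.pi)


def run_exhaustive_oracle(basis: ResponseBasis) -> np.ndarray:
    """Global optimum over all 2^M binary masks (M <= 16 only)."""
    m = basis.m_active
    if m > 16:
        raise ValueError("exhaustive search limited to M <= 16")
    codes = np.arange(2 ** m, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(m)[None, :]) & 1
    signs = 1.0 - 2.0 * bits
    f = signs @ basis.e_seg + basis.e_static
    best = int(np.argmax(np.sum(np.abs(f) ** 2, axis=1)))
    return np.where(bits[best] == 0, 0.0, np.pi)
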