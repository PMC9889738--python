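"""Calibrated Fourier-optics forward model: SLM state -> focal field -> detector.

The spatial light modulator (SLM) is conjugated to the rear pupil of a
low-NA focusing objective, so the focal field is the centred 2-D discrete
Fourier transform of the pupil field.  The grid is calibrated such that the
focal pixel pitch is

    pitch = wavelength * pupil_diameter_px / (2 * NA * grid_n)   [micron]

which places the FWHM of the unaberrated Airy focus at 0.514 * wavelength / NA
exactly (ideal filled circular pupil).

The SLM is segmented N x N over the square bounding the pupil disk; only the
segments whose cell centres fall inside the inscribed circle are active (the
area covered by the incident beam).  Each active segment carries one binary
phase in {0, pi}.  Because the focal field is linear in the per-segment
complex factors exp(j*b_i), the response of every segment can be precomputed
once (``ResponseBasis``) and any of the thousands of dither patterns then
costs a small matrix product instead of an FFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scatter_media import TransmissionMedium

__all__ = [
    "OpticalConfig",
    "SegmentLayout",
    "DetectionAperture",
    "ResponseBasis",
    "NoiseModel",
    "airy_fwhm_um",
    "build_segment_grid",
    "linear_layout",
    "pupil_mask",
    "propagate_to_focus",
    "precompute_segment_responses",
    "detect_intensity",
    "render_focal_image",
    "validate_binary_phases",
]

#: FWHM of the ideal Airy intensity profile in units of wavelength/NA.
AIRY_FWHM_FACTOR = 0.5145


@dataclass(frozen=True)
class OpticalConfig:
    """Optical geometry of the focusing arm.

    Defaults match a 589 nm beam focused by a 0.1-NA objective, simulated on
    a 256 x 256 grid with a 128-pixel pupil (2x oversampling of the speckle
    grain).  ``pupil_scale < 1`` underfills the pupil, enlarging the focus by
    ``1/pupil_scale`` (the low-NA route to a bigger stimulation spot).
    """

    wavelength_um: float = 0.589
    na: float = 0.1
    grid_n: int = 256
    pupil_diameter_px: int = 128
    pupil_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_n % 2 != 0:
            raise ValueError("grid_n must be even (centred DFT convention)")
        if not (0 < self.pupil_scale <= 1):
            raise ValueError("pupil_scale must be in (0, 1]")
        if self.pupil_diameter_px > self.grid_n // 2:
            raise ValueError(
                "pupil_diameter_px must be <= grid_n/2 "
                "(>=2x oversampling of the speckle grain)"
            )
        if self.wavelength_um <= 0 or self.na <= 0:
            raise ValueError("wavelength and NA must be positive")

    @property
    def focal_pixel_pitch(self) -> float:
        """Focal-plane pixel pitch in micron (exact calibration identity)."""
        return (self.wavelength_um * self.pupil_diameter_px
                / (2.0 * self.na * self.grid_n))


def airy_fwhm_um(config: OpticalConfig) -> float:
    """Diffraction-limited focus FWHM, 0.514*lambda/NA (filled pupil)."""
    return AIRY_FWHM_FACTOR * config.wavelength_um / (config.na * config.pupil_scale)


@dataclass(frozen=True)
class SegmentLayout:
    """N x N SLM segmentation with inscribed-circle active mask.

    ``segment_map`` labels each pupil-grid pixel with the index (0..M-1) of
    the active segment covering it, or -1 for static light.  ``linear``
    layouts (no pupil mapping) address transmission-matrix media whose input
    modes are the segments themselves.
    """

    n_side: int
    m_active: int
    active_rc: np.ndarray = field(repr=False)  # (M, 2) segment row/col, or empty
    segment_map: np.ndarray | None = field(default=None, repr=False)
    cell_px: int = 0

    @property
    def is_linear(self) -> bool:
        return self.segment_map is None and self.n_side == 0


def build_segment_grid(config: OpticalConfig, n_side: int) -> SegmentLayout:
    """Segment the pupil square N x N and keep the inscribed-circle segments.

    A segment (r, c) is active iff its cell centre lies within N/2 cells of
    the grid centre.  For N = 32 this yields M = 812 active segments
    (~ pi/4 * N^2).  Pupil pixels not covered by an active segment contribute
    static (unmodulated) light.
    """
    if n_side < 2 or n_side % 2 != 0:
        raise ValueError("segment grid side must be an even integer >= 2")
    cell = config.pupil_diameter_px // n_side
    if cell < 1:
        raise ValueError(
            f"N={n_side} too large for a {config.pupil_diameter_px}-pixel pupil"
        )
    side_px = n_side * cell
    origin = (config.grid_n - side_px) // 2

    r, c = np.mgrid[0:n_side, 0:n_side]
    d2 = (r + 0.5 - n_side / 2) ** 2 + (c + 0.5 - n_side / 2) ** 2
    active = d2 <= (n_side / 2) ** 2
    rc = np.argwhere(active)

    seg_map = np.full((config.grid_n, config.grid_n), -1, dtype=np.int32)
    for idx, (rr, cc) in enumerate(rc):
        r0 = origin + rr * cell
        c0 = origin + cc * cell
        seg_map[r0:r0 + cell, c0:c0 + cell] = idx

    return SegmentLayout(
        n_side=n_side, m_active=int(active.sum()), active_rc=rc,
        segment_map=seg_map, cell_px=cell,
    )


def linear_layout(m_active: int) -> SegmentLayout:
    """Trivial layout of ``m_active`` segments without a pupil mapping.

    Used with matrix-form media whose columns are the segment modes.
    """
    if m_active < 1:
        raise ValueError("m_active must be >= 1")
    return SegmentLayout(
        n_side=0, m_active=m_active,
        active_rc=np.empty((0, 2), dtype=int), segment_map=None,
    )


def pupil_mask(config: OpticalConfig) -> np.ndarray:
    """Boolean aperture disk (diameter ``pupil_scale * pupil_diameter_px``)."""
    n = config.grid_n
    c = n // 2
    x, y = np.mgrid[0:n, 0:n]
    radius = config.pupil_scale * config.pupil_diameter_px / 2.0
    return (x - c) ** 2 + (y - c) ** 2 <= radius ** 2


def propagate_to_focus(pupil_field: np.ndarray, config: OpticalConfig) -> np.ndarray:
    """Centred 2-D DFT of the pupil field, Parseval-normalised.

    ``out[u, v] = (1/n) * sum_xy in * exp(-2pi j ((u-c)(x-c)+(v-c)(y-c))/n)``
    with ``c = n//2``; total energy is conserved exactly.
    """
    n = config.grid_n
    if pupil_field.shape != (n, n):
        raise ValueError("pupil_field must be grid_n x grid_n")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pupil_field))) / n


@dataclass(frozen=True)
class DetectionAperture:
    """Feedback aperture in the focal plane (the pinhole / fibre face).

    ``center_um`` is (x, y) in micron, x along columns, y along rows, origin
    at the array centre pixel (index grid_n//2).  The aperture always covers
    at least the pixel nearest its centre.
    """

    center_um: tuple[float, float] = (0.0, 0.0)
    shape: str = "disk"
    radius_um: float = 1.0
    half_extents_um: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "rectangle"):
            raise ValueError("aperture shape must be 'disk' or 'rectangle'")

    def center_px(self, grid_n: int, pitch_um: float) -> tuple[int, int]:
        c = grid_n // 2
        col = int(round(c + self.center_um[0] / pitch_um))
        row = int(round(c + self.center_um[1] / pitch_um))
        if not (0 <= row < grid_n and 0 <= col < grid_n):
            raise ValueError("aperture centre falls outside the focal grid")
        return row, col

    def pixel_mask(self, grid_n: int, pitch_um: float) -> np.ndarray:
        c = grid_n // 2
        rows, cols = np.mgrid[0:grid_n, 0:grid_n]
        x = (cols - c) * pitch_um - self.center_um[0]
        y = (rows - c) * pitch_um - self.center_um[1]
        if self.shape == "disk":
            mask = x ** 2 + y ** 2 <= self.radius_um ** 2
        else:
            hx, hy = self.half_extents_um
            mask = (np.abs(x) <= hx) & (np.abs(y) <= hy)
        if not mask.any():
            mask[self.center_px(grid_n, pitch_um)] = True
        return mask


@dataclass
class NoiseModel:
    """Optional detector noise: Poisson shot noise at ``photons_per_unit``
    photons per intensity unit plus Gaussian read noise (intensity units)."""

    photons_per_unit: float = 0.0  # 0 -> no shot noise
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def apply(self, intensity: np.ndarray) -> np.ndarray:
        out = np.asarray(intensity, dtype=float)
        if self.photons_per_unit > 0:
            out = self._rng.poisson(out * self.photons_per_unit) / self.photons_per_unit
        if self.read_sigma > 0:
            out = out + self._rng.normal(0.0, self.read_sigma, size=np.shape(out))
        return out


@dataclass
class ResponseBasis:
    """Per-segment complex focal response at the detection pixels.

    The field for a binary state ``b`` is exactly
    ``E_static + sum_i exp(j b_i) E_i`` (linearity of the DFT), so detected
    intensities for whole dither sequences reduce to matrix products.  For
    screen-form media the full focal frame is rendered on demand from the
    pupil; matrix-form media render their output modes as a square image.
    """

    layout: SegmentLayout
    config: OpticalConfig
    aperture: DetectionAperture
    medium: TransmissionMedium
    e_seg: np.ndarray       # (M, n_det) complex
    e_static: np.ndarray    # (n_det,) complex
    det_rows: np.ndarray
    det_cols: np.ndarray

    @property
    def m_active(self) -> int:
        return self.layout.m_active

    def field_at_detector(self, state: np.ndarray) -> np.ndarray:
        state = validate_binary_phases(state, self.m_active)
        signs = np.where(state > np.pi / 2, -1.0, 1.0)
        return self.e_static + signs @ self.e_seg

    def detect(self, state: np.ndarray, noise: NoiseModel | None = None) -> float:
        f = self.field_at_detector(state)
        val = float(np.sum(np.abs(f) ** 2))
        if noise is not None:
            val = float(noise.apply(np.array(val)))
        return val

    def detect_series(self, sign_matrix: np.ndarray,
                      noise: NoiseModel | None = None) -> np.ndarray:
        """Detected intensity for each row of a (T, M) +/-1 sign matrix."""
        f = sign_matrix @ self.e_seg + self.e_static
        out = np.sum(np.abs(f) ** 2, axis=1)
        if noise is not None:
            out = noise.apply(out)
        return out

    def render(self, state: np.ndarray) -> np.ndarray:
        """Full focal-plane intensity image for a binary state."""
        state = validate_binary_phases(state, self.m_active)
        if self.medium.form == "matrix":
            phasors = np.exp(1j * state)
            out_field = self.medium.values @ phasors
            side = int(round(np.sqrt(out_field.size)))
            if side * side != out_field.size:
                raise ValueError(
                    "matrix medium n_out is not a perfect square; "
                    "cannot render a square focal image"
                )
            return np.abs(out_field.reshape(side, side)) ** 2
        pupil = _pupil_field_for_state(self.layout, self.medium, self.config, state)
        return np.abs(propagate_to_focus(pupil, self.config)) ** 2


def validate_binary_phases(state: np.ndarray, m_expected: int | None = None) -> np.ndarray:
    """Check that a mask/state holds only phases 0 or pi; returns float array."""
    arr = np.asarray(state, dtype=float)
    if m_expected is not None and arr.shape != (m_expected,):
        raise ValueError(f"state must have shape ({m_expected},), got {arr.shape}")
    ok = np.isclose(arr, 0.0) | np.isclose(arr, np.pi)
    if not ok.all():
        raise ValueError("binary SLM state must contain only 0 or pi")
    return arr


def _pupil_field_for_state(layout: SegmentLayout, medium: TransmissionMedium,
                           config: OpticalConfig, state: np.ndarray) -> np.ndarray:
    seg_map = layout.segment_map
    if seg_map is None:
        raise ValueError("layout carries no pupil mapping (linear layout)")
    phase = np.zeros((config.grid_n, config.grid_n))
    covered = seg_map >= 0
    phase[covered] = state[seg_map[covered]]
    return pupil_mask(config) * medium.values * np.exp(1j * phase)


def precompute_segment_responses(
    layout: SegmentLayout,
    medium: TransmissionMedium,
    config: OpticalConfig,
    aperture: DetectionAperture,
) -> ResponseBasis:
    """Compute each segment's complex field at the detection pixels.

    Matrix form: segment responses are the matrix columns restricted to the
    aperture's output modes (requires ``n_in == M``).  Screen form: a direct
    centred-DFT kernel over each segment's pupil pixels, exactly matching
    ``propagate_to_focus``.
    """
    if medium.form == "matrix":
        n_out, n_in = medium.values.shape
        if n_in != layout.m_active:
            raise ValueError(
                f"matrix medium has n_in={n_in}, layout has M={layout.m_active}"
            )
        side = int(round(np.sqrt(n_out)))
        if side * side != n_out:
            raise ValueError("matrix medium n_out must be a perfect square")
        mask = aperture.pixel_mask(side, config.focal_pixel_pitch)
        det_rows, det_cols = np.nonzero(mask)
        modes = det_rows * side + det_cols
        e_seg = medium.values[modes, :].T.copy()  # (M, n_det)
        e_static = np.zeros(len(modes), dtype=complex)
        return ResponseBasis(layout, config, aperture, medium,
                             e_seg, e_static, det_rows, det_cols)

    if layout.segment_map is None:
        raise ValueError("screen-form media require a pupil-mapped layout")
    n = config.grid_n
    if medium.values.shape != (n, n):
        raise ValueError("screen grid does not match config.grid_n")
    mask = aperture.pixel_mask(n, config.focal_pixel_pitch)
    det_rows, det_cols = np.nonzero(mask)
    c = n // 2

    pup = pupil_mask(config)
    seg_map = layout.segment_map
    in_seg = (seg_map >= 0) & pup
    px_r, px_c = np.nonzero(in_seg)
    seg_id = seg_map[px_r, px_c]
    order = np.argsort(seg_id, kind="stable")
    px_r, px_c, seg_id = px_r[order], px_c[order], seg_id[order]
    amp = medium.values[px_r, px_c]

    # direct centred-DFT kernel, identical to propagate_to_focus for even n
    ku = (det_rows[:, None] - c) * (px_r[None, :] - c)
    kv = (det_cols[:, None] - c) * (px_c[None, :] - c)
    kernel = np.exp(-2j * np.pi * (ku + kv) / n) / n  # (n_det, n_px)
    contrib = kernel * amp[None, :]

    m = layout.m_active
    e_seg = np.zeros((m, len(det_rows)), dtype=complex)
    boundaries = np.searchsorted(seg_id, np.arange(m + 1))
    for i in range(m):
        lo, hi = boundaries[i], boundaries[i + 1]
        if hi > lo:
            e_seg[i] = contrib[:, lo:hi].sum(axis=1)

    # static light: pupil pixels not covered by an active segment
    st_r, st_c = np.nonzero(pup & ~in_seg)
    if len(st_r):
        ku = (det_rows[:, None] - c) * (st_r[None, :] - c)
        kv = (det_cols[:, None] - c) * (st_c[None, :] - c)
        e_static = (np.exp(-2j * np.pi * (ku + kv) / n) / n
                    * medium.values[st_r, st_c][None, :]).sum(axis=1)
    else:
        e_static = np.zeros(len(det_rows), dtype=complex)

    return ResponseBasis(layout, config, aperture, medium,
                         e_seg, e_static, det_rows, det_cols)


def detect_intensity(basis: ResponseBasis, state: np.ndarray,
                     noise: NoiseModel | None = None) -> float:
    """Scalar feedback: total intensity over the aperture pixels."""
    return basis.detect(state, noise=noise)


def render_focal_image(basis: ResponseBasis, state: np.ndarray) -> np.ndarray:
    """Full focal-plane intensity image (arbitrary units)."""
    return basis.render(state)
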