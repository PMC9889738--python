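"""Focus-quality metrics: dark subtraction, bicubic upsampling, PBR, FWHM,
position error and decorrelation traces.

The pipeline order is fixed: subtract the camera dark offset, upsample the
image tenfold with bicubic interpolation, then measure.  PBR is the ratio
between the peak and the mean value of the background, the background being
the frame minus a disk (default radius three nominal FWHM) around the
target, so the metric is insensitive to the focus itself.  FWHM is read off
the horizontal and vertical section profiles through the peak; the headline
value is their mean.  The focus position is the peak-intensity point of the
interpolated image.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .forward_optics import (
    DetectionAperture,
    OpticalConfig,
    SegmentLayout,
    precompute_segment_responses,
)
from .scatter_media import TransmissionMedium, evolve_medium

__all__ = [
    "FocusReport",
    "subtract_dark",
    "interpolate_image",
    "compute_pbr",
    "default_pbr_regions",
    "quick_pbr",
    "compute_fwhm",
    "peak_position_um",
    "focus_position_error",
    "analyze_focus",
    "decorrelation_trace",
]

DEFAULT_DARK_OFFSET = 200.0
DEFAULT_INTERP_FACTOR = 10


@dataclass
class FocusReport:
    """Summary metrics of a focal image."""

    pbr: float
    fwhm_x_um: float
    fwhm_y_um: float
    fwhm_um: float              # mean of x and y sections (headline)
    peak_position_um: tuple[float, float]
    position_error_um: float
    background_mean: float
    peak_value: float

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def subtract_dark(image: np.ndarray, offset: float = DEFAULT_DARK_OFFSET) -> np.ndarray:
    """Remove the camera dark offset, clamping at zero."""
    if offset < 0:
        raise ValueError("dark offset must be >= 0")
    return np.maximum(np.asarray(image, dtype=float) - offset, 0.0)


def interpolate_image(image: np.ndarray, factor: int = DEFAULT_INTERP_FACTOR) -> np.ndarray:
    """Bicubic upsampling by ``factor`` along both axes.

    Uses cubic-convolution resampling (the interpolation of MATLAB's
    ``interp2``/ImageJ, bounded overshoot), not a cubic spline.  Output pixel
    ``u`` samples input coordinate ``(u + 0.5)/factor - 0.5`` (pixel-centre
    convention), so positions map back exactly.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(image, dtype=float)
    if factor == 1:
        return arr.copy()
    scale = arr.max() - arr.min()
    if scale == 0:
        return np.full((arr.shape[0] * factor, arr.shape[1] * factor), arr.flat[0])
    # normalise into float32's comfortable range before resampling
    lo = arr.min()
    norm = ((arr - lo) / scale).astype(np.float32)
    pim = Image.fromarray(norm, mode="F")
    out = pim.resize((arr.shape[1] * factor, arr.shape[0] * factor),
                     Image.Resampling.BICUBIC)
    return np.asarray(out, dtype=float) * scale + lo


def compute_pbr(image: np.ndarray, peak_region: np.ndarray,
                background_region: np.ndarray) -> float:
    """Peak over ``peak_region`` divided by mean over ``background_region``."""
    image = np.asarray(image, dtype=float)
    peak_region = np.asarray(peak_region, dtype=bool)
    background_region = np.asarray(background_region, dtype=bool)
    if (peak_region & background_region).any():
        raise ValueError("peak and background regions must be disjoint")
    if not background_region.any():
        raise ValueError("background region is empty")
    if not peak_region.any():
        raise ValueError("peak region is empty")
    return float(image[peak_region].max() / image[background_region].mean())


def default_pbr_regions(shape: tuple[int, int], target_px: tuple[float, float],
                        exclude_radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Peak disk around the target and its complement as background."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (rows - target_px[0]) ** 2 + (cols - target_px[1]) ** 2
    peak = d2 <= exclude_radius_px ** 2
    if not peak.any():
        peak[int(round(target_px[0])), int(round(target_px[1]))] = True
    return peak, ~peak


def quick_pbr(image: np.ndarray, target_px: tuple[float, float],
              exclude_radius_px: float) -> float:
    """PBR with the default disk-around-target region split."""
    peak, bg = default_pbr_regions(np.shape(image), target_px, exclude_radius_px)
    return compute_pbr(image, peak, bg)


def _profile_fwhm(profile: np.ndarray, peak_idx: int, background: float) -> float:
    """Width (in samples) at half of (peak - background) around ``peak_idx``."""
    peak_val = profile[peak_idx]
    half = background + 0.5 * (peak_val - background)
    if peak_val <= background:
        raise ValueError("no peak above background on the section line")

    def cross(direction: int) -> float:
        i = peak_idx
        while 0 <= i + direction < len(profile) and profile[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(profile):
            raise ValueError("half-maximum crossing not found (flat image?)")
        # linear interpolation between samples i and j
        frac = (profile[i] - half) / (profile[i] - profile[j])
        return i + direction * frac

    return cross(+1) - cross(-1)


def compute_fwhm(image: np.ndarray, pitch_um: float, axis: str = "x",
                 background: float = 0.0,
                 peak_px: tuple[int, int] | None = None) -> float:
    """FWHM (micron) of the section profile through the peak.

    ``pitch_um`` is the pixel pitch of ``image`` (pass pitch/factor for an
    interpolated image).  ``axis='x'`` takes the row through the peak
    (horizontal section), ``axis='y'`` the column.
    """
    image = np.asarray(image, dtype=float)
    if peak_px is None:
        peak_px = np.unravel_index(int(np.argmax(image)), image.shape)
    if axis == "x":
        profile, idx = image[peak_px[0], :], peak_px[1]
    elif axis == "y":
        profile, idx = image[:, peak_px[1]], peak_px[0]
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return _profile_fwhm(profile, idx, background) * pitch_um


def peak_position_um(image: np.ndarray, pitch_um: float,
                     factor: int = 1) -> tuple[float, float]:
    """Peak position (x, y) in micron, origin at the original array centre.

    ``factor`` is the interpolation factor already applied to ``image``.
    """
    image = np.asarray(image, dtype=float)
    pr, pc = np.unravel_index(int(np.argmax(image)), image.shape)
    # map interpolated pixel back to original pixel coordinates
    row = (pr + 0.5) / factor - 0.5
    col = (pc + 0.5) / factor - 0.5
    c = (image.shape[0] / factor) // 2
    return ((col - c) * pitch_um, (row - c) * pitch_um)


def focus_position_error(image: np.ndarray, target_um: tuple[float, float],
                         pitch_um: float, factor: int = 1) -> float:
    """Euclidean distance (micron) between the peak and the target."""
    x, y = peak_position_um(image, pitch_um, factor=factor)
    return float(np.hypot(x - target_um[0], y - target_um[1]))


def analyze_focus(
    image: np.ndarray,
    pitch_um: float,
    target_um: tuple[float, float] = (0.0, 0.0),
    dark_offset: float = 0.0,
    factor: int = DEFAULT_INTERP_FACTOR,
    exclude_radius_um: float | None = None,
    nominal_fwhm_um: float | None = None,
) -> FocusReport:
    """Full metric pipeline: dark subtraction -> interpolation -> metrics.

    ``exclude_radius_um`` bounds the peak/background split (default 3x
    ``nominal_fwhm_um``, falling back to 3 pixels).  Raw simulated images
    carry no dark offset, so ``dark_offset`` defaults to 0 here; camera-like
    stacks should pass 200.
    """
    img = subtract_dark(image, dark_offset) if dark_offset else np.asarray(image, float)
    interp = interpolate_image(img, factor)
    fine_pitch = pitch_um / factor

    if exclude_radius_um is None:
        exclude_radius_um = 3.0 * (nominal_fwhm_um if nominal_fwhm_um else pitch_um)

    c = img.shape[0] // 2
    target_px_interp = (
        ((c + target_um[1] / pitch_um) + 0.5) * factor - 0.5,
        ((c + target_um[0] / pitch_um) + 0.5) * factor - 0.5,
    )
    peak_reg, bg_reg = default_pbr_regions(
        interp.shape, target_px_interp, exclude_radius_um / fine_pitch
    )
    bg_mean = float(interp[bg_reg].mean())
    pbr = compute_pbr(interp, peak_reg, bg_reg)

    # peak restricted to the target neighbourhood for the section profiles
    masked = np.where(peak_reg, interp, -np.inf)
    peak_px = np.unravel_index(int(np.argmax(masked)), interp.shape)
    fx = compute_fwhm(interp, fine_pitch, axis="x", background=bg_mean, peak_px=peak_px)
    fy = compute_fwhm(interp, fine_pitch, axis="y", background=bg_mean, peak_px=peak_px)

    row = (peak_px[0] + 0.5) / factor - 0.5
    col = (peak_px[1] + 0.5) / factor - 0.5
    pos = ((col - c) * pitch_um, (row - c) * pitch_um)
    err = float(np.hypot(pos[0] - target_um[0], pos[1] - target_um[1]))

    return FocusReport(
        pbr=pbr,
        fwhm_x_um=fx,
        fwhm_y_um=fy,
        fwhm_um=0.5 * (fx + fy),
        peak_position_um=pos,
        position_error_um=err,
        background_mean=bg_mean,
        peak_value=float(interp[peak_px]),
    )


def decorrelation_trace(
    medium: TransmissionMedium,
    layout: SegmentLayout,
    config: OpticalConfig,
    aperture: DetectionAperture,
    mask: np.ndarray,
    duration_s: float,
    sample_period_s: float = 0.1,
) -> np.ndarray:
    """Peak-pixel intensity of a fixed correction as the medium evolves.

    Samples the detected intensity at the aperture every ``sample_period_s``
    (10 frames/s by default) for ``duration_s``, normalised to t = 0.  A
    static medium yields a flat trace.
    """
    n_steps = int(round(duration_s / sample_period_s))
    med = medium.copy()
    out = np.empty(n_steps + 1)
    for i in range(n_steps + 1):
        basis = precompute_segment_responses(layout, med, config, aperture)
        out[i] = basis.detect(mask)
        if i < n_steps:
            if np.isfinite(med.tau):
                med = evolve_medium(med, sample_period_s)
            else:
                med = med.copy()
                med.clock += sample_period_s
    if out[0] > 0:
        out = out / out[0]
    return out
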