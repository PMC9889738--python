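"""Synthetic wide-field calcium movies and dF/F quantification.

This module emulates the optogenetics readout: disk-shaped neurons expressing
a calcium indicator are illuminated by a (corrected or speckle) excitation
pattern, and each stimulation evokes a fluorescence transient whose amplitude
follows a sigmoidal dose-response in the light intensity delivered to the
soma.  A focus concentrating the same optical power onto the soma therefore
sits above the activation threshold while the corresponding speckle sits
below it -- the contrast the wavefront correction exists to create.

The transient kernel is a normalised double exponential
``(1 - exp(-t/tau_r)) * exp(-t/tau_d)`` scaled so its peak equals the
dose-response amplitude (in dF/F units).  Movies carry Poisson shot noise
and the camera dark offset (200 counts) so the analysis side has something
honest to remove.  dF/F uses the standard ``(F - F0)/F0`` with F0 the mean
over a pre-stimulus baseline window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulationProtocol",
    "NeuronSpec",
    "response_amplitude",
    "transient_kernel",
    "synth_calcium_movie",
    "extract_trace",
    "circular_roi",
    "compute_dff",
    "peak_response",
]

DARK_OFFSET = 200.0


@dataclass(frozen=True)
class StimulationProtocol:
    """Stimulation timing: 200 ms pulses every 5 s, nine pulses, imaged at
    10 frames/s, with a pre-stimulus baseline before the first pulse."""

    stim_duration_s: float = 0.2
    period_s: float = 5.0
    n_stims: int = 9
    frame_rate_hz: float = 10.0
    baseline_s: float = 3.0
    tail_s: float = 3.0

    def __post_init__(self) -> None:
        if self.period_s <= self.stim_duration_s:
            raise ValueError("stimulation period must exceed stimulus duration")
        if self.n_stims < 1:
            raise ValueError("need at least one stimulus")
        if self.frame_rate_hz <= 0 or self.baseline_s < 0:
            raise ValueError("invalid frame rate or baseline")

    @property
    def stim_onsets_s(self) -> np.ndarray:
        return self.baseline_s + self.period_s * np.arange(self.n_stims)

    @property
    def n_frames(self) -> int:
        total = self.baseline_s + self.period_s * self.n_stims + self.tail_s
        return int(round(total * self.frame_rate_hz))

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class NeuronSpec:
    """Disk-shaped neuron with a sigmoidal light dose-response.

    ``i_threshold`` is the illumination (intensity units, mean over the soma)
    at which the response reaches half its maximum ``a_max`` (dF/F units);
    ``slope`` sets the sigmoid width.  Rise must be faster than decay.
    """

    center_um: tuple[float, float] = (0.0, 0.0)
    radius_um: float = 8.0
    f0: float = 1000.0
    i_threshold: float = 1.0
    slope: float = 0.25
    a_max: float = 0.8
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.5

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("baseline fluorescence F0 must be positive")
        if not self.tau_rise_s < self.tau_decay_s:
            raise ValueError("rise time must be shorter than decay time")


def response_amplitude(intensity: float, neuron: NeuronSpec) -> float:
    """Sigmoidal dose-response: a_max / (1 + exp(-(I - I_th)/slope)).

    Strictly increasing in the delivered intensity; equals a_max/2 at the
    threshold and ~0 deep in the speckle regime.
    """
    if np.any(np.asarray(intensity) < 0):
        raise ValueError("intensity must be >= 0")
    z = (np.asarray(intensity, dtype=float) - neuron.i_threshold) / neuron.slope
    out = neuron.a_max / (1.0 + np.exp(-z))
    return float(out) if np.isscalar(intensity) else out


def transient_kernel(t_s: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Unit-peak double-exponential transient evaluated at times >= 0."""
    t = np.asarray(t_s, dtype=float)
    raw = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / tau_rise_s))
                   * np.exp(-np.maximum(t, 0) / tau_decay_s), 0.0)
    t_peak = tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)
    peak = (1.0 - np.exp(-t_peak / tau_rise_s)) * np.exp(-t_peak / tau_decay_s)
    return raw / peak


def _soma_mask(shape: tuple[int, int], pixel_um: float,
               center_um: tuple[float, float], radius_um: float) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = shape[0] // 2, shape[1] // 2
    x = (cols - cx) * pixel_um - center_um[0]
    y = (rows - cy) * pixel_um - center_um[1]
    return x ** 2 + y ** 2 <= radius_um ** 2


def mean_soma_illumination(illumination: np.ndarray, pixel_um: float,
                           neuron: NeuronSpec) -> float:
    mask = _soma_mask(illumination.shape, pixel_um, neuron.center_um,
                      neuron.radius_um)
    if not mask.any():
        return 0.0
    return float(np.asarray(illumination, dtype=float)[mask].mean())


def synth_calcium_movie(
    neurons: list[NeuronSpec],
    protocol: StimulationProtocol,
    illumination: np.ndarray,
    seed: int = 0,
    pixel_um: float = 2.0,
    shape: tuple[int, int] = (128, 128),
    shot_noise: bool = True,
) -> np.ndarray:
    """Render a wide-field movie of stimulated neurons.

    ``illumination`` is a focal intensity image on the movie grid (resampled
    by nearest pixel if shapes differ).  Every stimulus adds a transient of
    amplitude ``response_amplitude(mean soma illumination)``.  Pixel values
    are Poisson counts around ``F0 * (1 + dF/F)`` plus the dark offset.
    """
    if not neurons:
        raise ValueError("need at least one neuron")
    rng = np.random.default_rng(seed)
    illum = np.asarray(illumination, dtype=float)
    if illum.shape != shape:
        ri = np.clip((np.arange(shape[0]) * illum.shape[0] / shape[0]).astype(int),
                     0, illum.shape[0] - 1)
        ci = np.clip((np.arange(shape[1]) * illum.shape[1] / shape[1]).astype(int),
                     0, illum.shape[1] - 1)
        illum = illum[np.ix_(ri, ci)]

    times = protocol.frame_times_s
    clean = np.zeros((protocol.n_frames,) + shape)
    for neuron in neurons:
        amp = response_amplitude(
            mean_soma_illumination(illum, pixel_um, neuron), neuron)
        dff = np.zeros(protocol.n_frames)
        for onset in protocol.stim_onsets_s:
            dff += amp * transient_kernel(times - onset, neuron.tau_rise_s,
                                          neuron.tau_decay_s)
        mask = _soma_mask(shape, pixel_um, neuron.center_um, neuron.radius_um)
        clean[:, mask] += neuron.f0 * (1.0 + dff)[:, None]

    if shot_noise:
        movie = rng.poisson(clean).astype(float)
    else:
        movie = clean
    return movie + DARK_OFFSET


def circular_roi(shape: tuple[int, int], center_px: tuple[float, float],
                 radius_px: float) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rows - center_px[0]) ** 2 + (cols - center_px[1]) ** 2
            <= radius_px ** 2)


def extract_trace(stack: np.ndarray, roi: np.ndarray,
                  background_roi: np.ndarray) -> np.ndarray:
    """Per-frame mean over the neuron ROI minus mean over a blank-area ROI."""
    stack = np.asarray(stack, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if roi.shape != stack.shape[1:] or background_roi.shape != stack.shape[1:]:
        raise ValueError("ROIs must match the frame shape")
    if not roi.any() or not background_roi.any():
        raise ValueError("ROIs must be non-empty")
    if (roi & background_roi).any():
        warnings.warn("neuron and background ROIs overlap", RuntimeWarning)
    return stack[:, roi].mean(axis=1) - stack[:, background_roi].mean(axis=1)


def compute_dff(trace: np.ndarray, baseline_window: tuple[int, int]) -> np.ndarray:
    """(F - F0)/F0 with F0 the mean over ``baseline_window`` frames."""
    trace = np.asarray(trace, dtype=float)
    lo, hi = baseline_window
    if not (0 <= lo < hi <= len(trace)):
        raise ValueError("baseline window must lie inside the trace")
    f0 = trace[lo:hi].mean()
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    return (trace - f0) / f0


def peak_response(dff: np.ndarray, protocol: StimulationProtocol,
                  window_s: float = 3.0) -> dict:
    """Max dF/F in a post-stimulus window, per stimulus, with mean +/- SE."""
    dff = np.asarray(dff, dtype=float)
    fr = protocol.frame_rate_hz
    peaks = []
    for onset in protocol.stim_onsets_s:
        lo = int(round(onset * fr))
        hi = int(round((onset + window_s) * fr))
        if hi > len(dff):
            raise ValueError("response window extends past the trace")
        peaks.append(float(dff[lo:hi].max()))
    peaks = np.asarray(peaks)
    se = float(peaks.std(ddof=1) / np.sqrt(len(peaks))) if len(peaks) > 1 else 0.0
    return {"peaks": peaks, "mean": float(peaks.mean()), "se": se}
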