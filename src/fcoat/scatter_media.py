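"""Synthetic scattering media with controllable speckle statistics and dynamics.

Two interchangeable representations of a scatterer are provided:

``matrix``
    A complex transmission matrix with independent circular-Gaussian entries
    of unit mean squared magnitude.  This is the canonical statistical model
    of a thick, fully developed scatterer: any fixed input produces
    exponentially distributed output intensities (fully developed speckle),
    and enhancement theory for wavefront shaping is exact in this model.

``phase_screen``
    A thin random phase screen ``exp(j*g)`` on the pupil grid, with ``g`` a
    Gaussian random field of configurable RMS (``strength``, radians) and
    autocorrelation half-width (``correlation_length``, pupil pixels).
    Because the screen lives in a calibrated Fourier-optics model it yields
    focal-plane metrics (FWHM, position error) in physical units.

Temporal decorrelation — the reason a correction through living tissue decays —
is modelled as a stationary stochastic relaxation with an exponential field
autocorrelation ``exp(-dt/tau)``:

* matrix form: complex Ornstein-Uhlenbeck interpolation toward fresh draws,
  ``T' = T*sqrt(1-a) + sqrt(a)*T_fresh`` with ``a = 1 - exp(-2*dt/tau)``;
* screen form: Brownian phase walk ``g' = g + sqrt(2*dt/tau)*w`` with ``w`` a
  fresh unit-RMS correlated field, which keeps the screen pure-phase while
  giving exactly ``<exp(j(g'-g))> = exp(-dt/tau)``.

Both updates compose: evolving by ``dt1`` then ``dt2`` is statistically
identical to evolving once by ``dt1 + dt2``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TransmissionMedium",
    "make_transmission_matrix",
    "make_phase_screen",
    "evolve_medium",
    "field_correlation",
    "save_medium",
    "load_medium",
]

_EVOLVE_STREAM = 0xE404  # fixed sub-stream tag so evolution RNG != draw RNG


@dataclass
class TransmissionMedium:
    """A synthetic scatterer plus its decorrelation clock.

    Attributes
    ----------
    form : {"matrix", "phase_screen"}
    values : complex ndarray
        ``(n_out, n_in)`` transmission matrix, or ``(grid_n, grid_n)``
        unit-magnitude screen.
    tau : float
        Field decorrelation time in seconds (``inf`` for a static medium).
    seed : int
        Seed the medium was drawn from (recorded for provenance).
    clock : float
        Seconds of evolution applied so far.
    correlation_length : float or None
        Autocorrelation half-width of the screen phase, pupil pixels
        (screen form only).
    strength : float or None
        RMS of the screen phase at construction, radians (screen form only).
    """

    form: str
    values: np.ndarray
    tau: float = np.inf
    seed: int = 0
    clock: float = 0.0
    correlation_length: float | None = None
    strength: float | None = None
    _evo_rng: np.random.Generator | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.form not in ("matrix", "phase_screen"):
            raise ValueError(f"unknown medium form {self.form!r}")
        if not self.tau > 0:
            raise ValueError("decorrelation time tau must be > 0")
        if self.clock < 0:
            raise ValueError("clock must be >= 0")
        if self._evo_rng is None:
            self._evo_rng = np.random.default_rng([_EVOLVE_STREAM, self.seed])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def copy(self) -> "TransmissionMedium":
        # snapshot the evolution stream so copies evolve reproducibly and
        # independently of the original
        rng = np.random.default_rng(0)
        rng.bit_generator.state = self._evo_rng.bit_generator.state
        return dataclasses.replace(self, values=self.values.copy(), _evo_rng=rng)


def make_transmission_matrix(n_out: int, n_in: int, seed: int = 0,
                             tau: float = np.inf) -> TransmissionMedium:
    """Draw an ``n_out x n_in`` complex-Gaussian transmission matrix.

    Entries are independent circular Gaussians with ``E|T|^2 = 1`` (variance
    split equally between real and imaginary parts).
    """
    if n_out < 1 or n_in < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    t = rng.standard_normal((n_out, n_in)) + 1j * rng.standard_normal((n_out, n_in))
    t *= np.sqrt(0.5)
    return TransmissionMedium(form="matrix", values=t, tau=tau, seed=seed)


def _correlated_field(grid_n: int, correlation_length: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS, zero-mean Gaussian field with Gaussian autocorrelation of
    half-width (lag of 0.5 correlation) ``correlation_length`` pixels."""
    white = rng.standard_normal((grid_n, grid_n))
    # Gaussian smoothing kernel sigma such that the field autocorrelation
    # exp(-r^2 / (4 sigma^2)) crosses 1/2 at r = correlation_length.
    sigma = correlation_length / (2.0 * np.sqrt(np.log(2.0)))
    g = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    g -= g.mean()
    sd = g.std()
    if sd > 0:
        g /= sd
    return g


def make_phase_screen(grid_n: int, correlation_length: float = 2.0,
                      strength: float = 2.0 * np.pi, seed: int = 0,
                      tau: float = np.inf) -> TransmissionMedium:
    """Thin random phase screen ``exp(j*g)`` on a ``grid_n x grid_n`` pupil grid.

    ``strength`` is the RMS of the phase ``g`` in radians; a larger strength
    and/or shorter ``correlation_length`` stands in for thicker tissue.
    ``strength=0`` gives the identity screen (no aberration).
    """
    if grid_n < 16:
        raise ValueError("grid_n must be >= 16")
    if correlation_length < 1:
        raise ValueError("correlation_length must be >= 1 pixel")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        screen = np.ones((grid_n, grid_n), dtype=complex)
    else:
        rng = np.random.default_rng(seed)
        g = strength * _correlated_field(grid_n, correlation_length, rng)
        screen = np.exp(1j * g)
    return TransmissionMedium(
        form="phase_screen", values=screen, tau=tau, seed=seed,
        correlation_length=float(correlation_length), strength=float(strength),
    )


def evolve_medium(medium: TransmissionMedium, dt: float) -> TransmissionMedium:
    """Advance the medium by ``dt`` seconds of stochastic decorrelation.

    Returns a new medium whose field correlation with the input is
    ``exp(-dt/tau)`` in expectation; the clock advances by ``dt``.  Requires a
    finite ``tau`` (a static medium has nothing to evolve; ``dt = 0`` is
    always allowed and returns an identical copy).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    out = medium.copy()
    out.clock = medium.clock + dt
    if dt == 0:
        return out
    if not np.isfinite(medium.tau):
        raise ValueError("evolve_medium requires a finite decorrelation time tau")
    rng = out._evo_rng
    if medium.form == "matrix":
        alpha = 1.0 - np.exp(-2.0 * dt / medium.tau)
        n_out, n_in = medium.values.shape
        fresh = (rng.standard_normal((n_out, n_in))
                 + 1j * rng.standard_normal((n_out, n_in))) * np.sqrt(0.5)
        out.values = medium.values * np.sqrt(1.0 - alpha) + np.sqrt(alpha) * fresh
    else:
        grid_n = medium.values.shape[0]
        w = _correlated_field(grid_n, medium.correlation_length or 1.0, rng)
        out.values = medium.values * np.exp(1j * np.sqrt(2.0 * dt / medium.tau) * w)
    return out


def field_correlation(a: TransmissionMedium, b: TransmissionMedium) -> float:
    """Normalised modulus of the complex inner product of two media's values.

    Equals 1 for identical fields, ~0 for independent ones, and decays as
    ``exp(-dt/tau)`` between a medium and its evolved version.
    """
    if a.form != b.form or a.values.shape != b.values.shape:
        raise ValueError("media must share form and shape")
    va, vb = a.values.ravel(), b.values.ravel()
    denom = np.sqrt(np.mean(np.abs(va) ** 2) * np.mean(np.abs(vb) ** 2))
    if denom == 0:
        return 0.0
    return float(np.abs(np.mean(va * np.conj(vb))) / denom)


def save_medium(medium: TransmissionMedium, path) -> None:
    """Serialise a medium to a single ``.npz`` container with metadata."""
    np.savez(
        path,
        values=medium.values,
        form=np.array(medium.form),
        tau=np.array(medium.tau),
        seed=np.array(medium.seed),
        clock=np.array(medium.clock),
        correlation_length=np.array(
            np.nan if medium.correlation_length is None else medium.correlation_length
        ),
        strength=np.array(np.nan if medium.strength is None else medium.strength),
    )


def load_medium(path) -> TransmissionMedium:
    with np.load(path, allow_pickle=False) as z:
        corr = float(z["correlation_length"])
        strength = float(z["strength"])
        return TransmissionMedium(
            form=str(z["form"]),
            values=z["values"],
            tau=float(z["tau"]),
            seed=int(z["seed"]),
            clock=float(z["clock"]),
            correlation_length=None if np.isnan(corr) else corr,
            strength=None if np.isnan(strength) else strength,
        )
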