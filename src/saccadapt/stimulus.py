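"""Grating displays, windows, noise masks, and saccadic phase arithmetic.

The experimental manipulation lives entirely in one dimension: two
horizontal luminance gratings (one per half-screen) share a common spatial
phase, and a horizontal saccade of a chosen amplitude shifts the retinal
image by an integer number of cycles of one grating (the *correlated*
grating, phase shift ``0 mod 2*pi``) and by a half-integer number of cycles
of the other (the *anticorrelated* grating, phase shift ``pi``). This
module renders those displays and computes the phase consequences of a
given gaze displacement.

Canonical representation is a 1-D luminance profile along the axis of
interest; full 2-D frames are derived views assembled from profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when a stimulus parameter violates its physical constraints."""


# --------------------------------------------------------------------------
# display geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplayGeometry:
    """Physical monitor model: size, resolution, viewing distance, luminances.

    Defaults describe a 51.5 x 29 cm grayscale display at 1920 x 1080 px
    viewed from 60 cm, with black/grey/white luminances of 0.21, 58.33 and
    105.70 cd/m^2.

    Degrees of visual angle are measured from the screen center with a
    tangent mapping (no small-angle approximation), rightward and upward
    positive, so the deg<->px conversion is exactly invertible.
    """

    width_cm: float = 51.5
    height_cm: float = 29.0
    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_cm: float = 60.0
    luminance_black: float = 0.21
    luminance_white: float = 105.70
    luminance_grey: float = 58.33

    def __post_init__(self) -> None:
        if not (self.luminance_black < self.luminance_grey < self.luminance_white):
            raise InvalidParameterError(
                "luminances must satisfy black < grey < white, got "
                f"{self.luminance_black}, {self.luminance_grey}, {self.luminance_white}"
            )
        if self.viewing_distance_cm <= 0:
            raise InvalidParameterError("viewing distance must be positive")

    @property
    def width_deg(self) -> float:
        return 2.0 * np.degrees(np.arctan2(self.width_cm / 2.0, self.viewing_distance_cm))

    @property
    def height_deg(self) -> float:
        return 2.0 * np.degrees(np.arctan2(self.height_cm / 2.0, self.viewing_distance_cm))

    def deg_to_cm(self, deg):
        return self.viewing_distance_cm * np.tan(np.radians(deg))

    def cm_to_deg(self, cm):
        return np.degrees(np.arctan2(cm, self.viewing_distance_cm))

    def deg_to_px(self, deg, axis: Literal["x", "y"] = "x"):
        """Degrees from screen center -> pixel offset from screen center."""
        per_px = (self.width_cm / self.width_px) if axis == "x" else (self.height_cm / self.height_px)
        return self.deg_to_cm(deg) / per_px

    def px_to_deg(self, px, axis: Literal["x", "y"] = "x"):
        per_px = (self.width_cm / self.width_px) if axis == "x" else (self.height_cm / self.height_px)
        return self.cm_to_deg(np.asarray(px) * per_px)


# --------------------------------------------------------------------------
# stimulus component specifications
# --------------------------------------------------------------------------

Waveform = Literal["sinusoid", "square"]


@dataclass(frozen=True)
class GratingSpec:
    """One horizontal luminance grating occupying one half of the display.

    ``wavelength_deg`` is the spatial period; ``phase_rad`` is the common
    phase shared by both half-screen gratings (jittered per trial in
    ``[-pi/2, pi/2]``); ``contrast`` is Michelson contrast.
    """

    wavelength_deg: float
    phase_rad: float = 0.0
    contrast: float = 0.5
    half: Literal["upper", "lower"] = "upper"
    role: Literal["correlated", "anticorrelated"] = "correlated"
    waveform: Waveform = "sinusoid"

    def __post_init__(self) -> None:
        if self.wavelength_deg <= 0:
            raise InvalidParameterError(f"wavelength must be positive, got {self.wavelength_deg}")
        if not 0.0 <= self.contrast <= 1.0:
            raise InvalidParameterError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.waveform not in ("sinusoid", "square"):
            raise InvalidParameterError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class WindowSpec:
    """Generalised-Gaussian spatial window ``exp(-(|y - y0| / alpha)**beta)``.

    With ``inverted=True`` the window *removes* contrast at its center
    (grating attenuated toward grey there), producing a grey bar whose
    edges blend smoothly into the gratings -- the separator between the
    two half-screen gratings (``alpha = 2.1`` deg, ``beta = 3``). The
    non-inverted form (``beta = 5``) cuts a visible slice out of a noise
    mask, retaining full grating contrast at its center.
    """

    scale_deg: float = 2.1
    shape: float = 3.0
    center_deg: float = 0.0
    orientation: Literal["horizontal", "vertical"] = "horizontal"
    inverted: bool = True

    def __post_init__(self) -> None:
        if self.scale_deg <= 0:
            raise InvalidParameterError(f"window scale must be positive, got {self.scale_deg}")
        if self.shape < 1:
            raise InvalidParameterError(f"window shape must be >= 1, got {self.shape}")

    def attenuation(self, positions_deg):
        """Fraction of grating contrast retained at each position."""
        core = np.exp(-(np.abs(np.asarray(positions_deg, dtype=float) - self.center_deg)
                        / self.scale_deg) ** self.shape)
        return 1.0 - core if self.inverted else core


@dataclass
class DisplayFrame:
    """A rendered luminance field with its axes in degrees of visual angle."""

    luminance: np.ndarray           # 2-D array, rows = y (top to bottom), cols = x
    x_deg: np.ndarray
    y_deg: np.ndarray
    kind: Literal["adaptation", "test", "mask", "blank"] = "test"
    fixation_positions_deg: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance, dtype=float)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def anticorrelated_wavelength(lambda_corr: float, f_anti: float) -> float:
    """Wavelength of the anticorrelated grating: ``2 * lambda_corr / f_anti``.

    A saccade of amplitude ``2 * lambda_corr`` then spans exactly ``f_anti``
    cycles of this grating; half-integer ``f_anti`` (1.5 or 2.5 in the
    design) leaves a half-cycle remainder, i.e. phase inversion.
    """
    if lambda_corr <= 0:
        raise InvalidParameterError(f"wavelength must be positive, got {lambda_corr}")
    if f_anti <= 0:
        raise InvalidParameterError(f"anticorrelation factor must be positive, got {f_anti}")
    return 2.0 * lambda_corr / f_anti


def split_contrast(mean_contrast: float, delta_c: float) -> tuple[float, float]:
    """Split a mean contrast into (c_corr, c_anti) with ``c_anti - c_corr = delta_c``.

    Symmetric split: ``c_corr = mean - delta_c/2``, ``c_anti = mean + delta_c/2``,
    the unique split preserving the stated constant mean.
    """
    c_corr = mean_contrast - delta_c / 2.0
    c_anti = mean_contrast + delta_c / 2.0
    for name, c in (("c_corr", c_corr), ("c_anti", c_anti)):
        if not 0.0 <= c <= 1.0 + 1e-12:
            raise InvalidParameterError(
                f"{name} = {c:.4f} outside [0, 1] for mean {mean_contrast}, delta {delta_c}"
            )
    return min(c_corr, 1.0), min(c_anti, 1.0)


def _waveform(phase: np.ndarray, waveform: Waveform) -> np.ndarray:
    if waveform == "sinusoid":
        return np.sin(phase)
    # square wave bounded in [-1, 1]; sign of the sinusoid, zeros kept at 0
    return np.sign(np.sin(phase))


def grating_profile(spec: GratingSpec, x_deg, geometry: DisplayGeometry) -> np.ndarray:
    """Luminance profile ``L(x) = L_grey * (1 + c * w(2 pi x / lambda + phi))``.

    At contrast 1 the extrema reach the display's white and black levels
    (up to the small asymmetry of the physical grey point).
    """
    x = np.asarray(x_deg, dtype=float)
    phase = 2.0 * np.pi * x / spec.wavelength_deg + spec.phase_rad
    return geometry.luminance_grey * (1.0 + spec.contrast * _waveform(phase, spec.waveform))


def apply_window(profile, positions_deg, window: WindowSpec,
                 geometry: DisplayGeometry) -> np.ndarray:
    """Attenuate a luminance profile toward grey according to a window.

    The window acts on contrast (deviation from grey), so an inverted
    window yields pure grey at its center and full contrast far away
    (attenuation of residual contrast < 1% beyond ~5 scale lengths for
    shape >= 3).
    """
    profile = np.asarray(profile, dtype=float)
    att = window.attenuation(positions_deg)
    return geometry.luminance_grey + (profile - geometry.luminance_grey) * att


def retinal_phase_shift(displacement_deg: float, wavelength_deg: float) -> float:
    """Phase shift of the retinal image of a grating after a gaze shift.

    Returns ``(2 pi * displacement / wavelength) mod 2 pi``; 0 means the
    postsaccadic retinal pattern is identical (correlated), pi means it is
    inverted -- white becomes black and vice versa (anticorrelated).
    """
    if wavelength_deg <= 0:
        raise InvalidParameterError(f"wavelength must be positive, got {wavelength_deg}")
    cycles = np.mod(displacement_deg / wavelength_deg, 1.0)
    if cycles > 1.0 - 1e-12:  # rounding pushed an integer cycle count just below 1
        cycles = 0.0
    return float(2.0 * np.pi * cycles)


def make_noise_mask(mean_sf: float = 0.18, sf_sd: float = 0.02, contrast: float = 0.7,
                    seed: int | np.random.Generator = 0,
                    geometry: DisplayGeometry | None = None,
                    samples_per_deg: float = 4.0) -> DisplayFrame:
    """Full-screen Gaussian-filtered white-noise mask.

    White noise is shaped in the frequency domain by a radial Gaussian
    amplitude envelope centered on ``mean_sf`` cyc/deg with width ``sf_sd``,
    so the amplitude spectrum peaks at the target spatial frequency and the
    amplitude-weighted mean radial frequency lands inside the
    ``mean_sf +/- sf_sd`` band. The result is normalised to the requested
    Michelson contrast around the display grey and is reproducible given
    the seed.
    """
    if not 0.0 <= contrast <= 1.0:
        raise InvalidParameterError(f"contrast must be in [0, 1], got {contrast}")
    geometry = geometry or DisplayGeometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    nx = max(8, int(round(geometry.width_deg * samples_per_deg)))
    ny = max(8, int(round(geometry.height_deg * samples_per_deg)))
    x_deg = np.arange(nx) / samples_per_deg - geometry.width_deg / 2.0
    y_deg = np.arange(ny) / samples_per_deg - geometry.height_deg / 2.0

    if contrast == 0.0:
        lum = np.full((ny, nx), geometry.luminance_grey)
        return DisplayFrame(lum, x_deg, y_deg, kind="mask")

    white = rng.standard_normal((ny, nx))
    fx = np.fft.fftfreq(nx, d=1.0 / samples_per_deg)
    fy = np.fft.fftfreq(ny, d=1.0 / samples_per_deg)
    f_rad = np.hypot(*np.meshgrid(fx, fy))
    envelope = np.exp(-((f_rad - mean_sf) ** 2) / (2.0 * sf_sd ** 2))
    envelope[0, 0] = 0.0  # no DC: mask fluctuates around grey
    shaped = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    shaped /= np.max(np.abs(shaped))

    lum = geometry.luminance_grey * (1.0 + contrast * shaped)
    return DisplayFrame(lum, x_deg, y_deg, kind="mask")


def spectral_centroid(frame: DisplayFrame, samples_per_deg: float | None = None) -> float:
    """Amplitude-weighted mean radial spatial frequency of a frame (cyc/deg).

    Computed from the 2-D discrete Fourier amplitude spectrum of the
    luminance deviation from its mean, DC excluded.
    """
    lum = frame.luminance
    ny, nx = lum.shape
    if samples_per_deg is None:
        samples_per_deg = 1.0 / float(np.mean(np.diff(frame.x_deg)))
    spec = np.abs(np.fft.fft2(lum - lum.mean()))
    fx = np.fft.fftfreq(nx, d=1.0 / samples_per_deg)
    fy = np.fft.fftfreq(ny, d=1.0 / samples_per_deg)
    f_rad = np.hypot(*np.meshgrid(fx, fy))
    return float(np.sum(f_rad * spec) / np.sum(spec))


def render_test_display(upper: GratingSpec, lower: GratingSpec,
                        geometry: DisplayGeometry | None = None,
                        separator: WindowSpec | None = None,
                        samples_per_deg: float = 4.0,
                        kind: Literal["adaptation", "test"] = "test") -> DisplayFrame:
    """Assemble a two-grating display with the grey separator bar.

    The upper grating fills the upper half, the lower grating the lower
    half, and an inverted horizontal window centered on the midline blends
    both into a grey bar.
    """
    geometry = geometry or DisplayGeometry()
    separator = separator or WindowSpec()
    nx = max(8, int(round(geometry.width_deg * samples_per_deg)))
    ny = max(8, int(round(geometry.height_deg * samples_per_deg)))
    x_deg = np.arange(nx) / samples_per_deg - geometry.width_deg / 2.0
    y_deg = np.arange(ny) / samples_per_deg - geometry.height_deg / 2.0

    upper_profile = grating_profile(upper, x_deg, geometry)
    lower_profile = grating_profile(lower, x_deg, geometry)
    lum = np.where(y_deg[:, None] >= 0, upper_profile[None, :], lower_profile[None, :])
    att = separator.attenuation(y_deg)[:, None]
    lum = geometry.luminance_grey + (lum - geometry.luminance_grey) * att
    return DisplayFrame(lum, x_deg, y_deg, kind=kind)
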