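"""Off-axis hologram reconstruction and dry-mass calibration.

An off-axis hologram encodes the object phase on a spatial carrier fringe
pattern.  Reconstruction follows the standard Fourier carrier-removal
chain: 2-D FFT of the intensity, extraction of the +1 sideband with a
window centred at the carrier frequency, translation of the sideband to
the frequency origin, inverse FFT, and the argument of the resulting
complex amplitude as the wrapped phase.  The wrapped phase is unwrapped
with a standard 2-D unwrapper and residual instrument aberrations are
removed by subtracting a low-order polynomial surface fitted to cell-free
background pixels.

Phase maps to dry-mass surface density through the refraction increment
gamma (~0.18-0.21 ml/g for cellular protein):

    rho(x, y) = lambda * phi(x, y) / (2 * pi * gamma)   [pg / um^2]

with lambda the illumination wavelength in um and phi in radians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.restoration import unwrap_phase as _skimage_unwrap

__all__ = [
    "Hologram",
    "PhaseImage",
    "ReconstructionConfig",
    "IllPosedCarrierError",
    "InsufficientBackgroundError",
    "DEFAULT_WAVELENGTH_UM",
    "DEFAULT_GAMMA_ML_PER_G",
    "detect_carrier",
    "reconstruct_wrapped_phase",
    "unwrap_phase",
    "compensate_background",
    "phase_to_dry_mass",
]

#: Illumination wavelength of the reference instrument (650 nm interference
#: filter), used as the package-wide default.
DEFAULT_WAVELENGTH_UM = 0.65

#: Refraction increment default: midpoint of the printed 0.18-0.21 ml/g range.
DEFAULT_GAMMA_ML_PER_G = 0.20

RADIANS = "radians"
PG_PER_UM2 = "pg_per_um2"


class IllPosedCarrierError(ValueError):
    """Carrier peak indistinguishable from the zero-order lobe."""


class InsufficientBackgroundError(ValueError):
    """Fewer background pixels than polynomial coefficients to fit."""


@dataclass
class Hologram:
    """Recorded off-axis interference intensity.

    Parameters
    ----------
    intensity : ndarray
        2-D non-negative real intensity map.
    carrier_frequency : tuple of float, optional
        Spatial carrier in cycles/pixel as (f_row, f_col).  When absent it
        is detected from the spectrum at reconstruction time.
    pixel_size_um : float
        Physical pixel pitch in the object plane.
    """

    intensity: np.ndarray
    carrier_frequency: Optional[Tuple[float, float]] = None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be 2-D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.carrier_frequency is not None:
            mag = float(np.hypot(*self.carrier_frequency))
            if not (0.0 < mag < 0.5):
                raise ValueError(
                    "carrier magnitude must lie in (0, 0.5) cycles/pixel"
                )


@dataclass
class PhaseImage:
    """2-D phase delay map (radians) or dry-mass density map (pg/um^2)."""

    values: np.ndarray
    units: str = RADIANS
    wavelength_um: float = DEFAULT_WAVELENGTH_UM
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phase values must be 2-D")
        if self.units not in (RADIANS, PG_PER_UM2):
            raise ValueError(f"unknown units {self.units!r}")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class ReconstructionConfig:
    """Parameters of the carrier-removal reconstruction chain.

    window_radius : float or None
        Radius of the circular spectral window in cycles/pixel.  ``None``
        selects 0.6x the carrier magnitude, which keeps the window clear of
        the zero-order term.
    compensation_degree : int
        Order of the polynomial background (compensation) surface.
    gamma_ml_per_g : float
        Refraction increment used for the dry-mass conversion.
    apodize : bool
        Replace the hard circular window with a raised-cosine edge.
    """

    window_radius: Optional[float] = None
    compensation_degree: int = 2
    gamma_ml_per_g: float = DEFAULT_GAMMA_ML_PER_G
    apodize: bool = False

    def __post_init__(self) -> None:
        if self.window_radius is not None and self.window_radius <= 0:
            raise ValueError("window_radius must be positive")
        if self.compensation_degree < 0:
            raise ValueError("compensation_degree must be >= 0")
        if not (0.18 <= self.gamma_ml_per_g <= 0.21):
            raise ValueError("gamma_ml_per_g must lie in [0.18, 0.21] ml/g")


def _freq_grids(shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    return fr, fc


def detect_carrier(intensity: np.ndarray, min_offset_bins: int = 3) -> Tuple[float, float]:
    """Locate the off-origin spectral peak of an off-axis hologram.

    Returns the carrier frequency in cycles/pixel (row, col).  Raises
    :class:`IllPosedCarrierError` when no sideband stands clear of the
    zero-order lobe.
    """
    intensity = np.asarray(intensity, dtype=float)
    spec = np.abs(np.fft.fft2(intensity - intensity.mean()))
    fr, fc = _freq_grids(spec.shape)
    # exclude a small disc around DC where the zero-order term lives
    r_excl = max(min_offset_bins / spec.shape[0], min_offset_bins / spec.shape[1])
    dist = np.hypot(fr, fc)
    spec = np.where(dist <= r_excl, 0.0, spec)
    idx = np.unravel_index(int(np.argmax(spec)), spec.shape)
    peak = spec[idx]
    if peak <= 0:
        raise IllPosedCarrierError("no off-origin spectral peak found")
    floor = np.median(spec[spec > 0])
    if peak < 10.0 * floor:
        raise IllPosedCarrierError(
            "carrier peak indistinguishable from the zero-order lobe"
        )
    f_row = float(np.fft.fftfreq(spec.shape[0])[idx[0]])
    f_col = float(np.fft.fftfreq(spec.shape[1])[idx[1]])
    # conjugate sidebands are equivalent; pick the one in the upper half-plane
    if f_row < 0 or (f_row == 0 and f_col < 0):
        f_row, f_col = -f_row, -f_col
    return (f_row, f_col)


def reconstruct_wrapped_phase(
    holo: Hologram, cfg: Optional[ReconstructionConfig] = None
) -> PhaseImage:
    """Extract the wrapped object phase from an off-axis hologram.

    The sideband is selected by a circular window centred at the carrier,
    demodulated to the frequency origin, and inverse transformed; the
    returned values are the argument of the complex amplitude, in
    (-pi, pi].
    """
    cfg = cfg or ReconstructionConfig()
    carrier = holo.carrier_frequency or detect_carrier(holo.intensity)
    f_mag = float(np.hypot(*carrier))
    radius = cfg.window_radius if cfg.window_radius is not None else 0.6 * f_mag
    if radius >= f_mag:
        raise IllPosedCarrierError(
            f"window radius {radius:.4f} reaches the zero-order term "
            f"(carrier magnitude {f_mag:.4f})"
        )
    spec = np.fft.fft2(holo.intensity)
    fr, fc = _freq_grids(spec.shape)
    dist = np.hypot(fr - carrier[0], fc - carrier[1])
    if cfg.apodize:
        window = np.clip((radius - dist) / (0.2 * radius), 0.0, 1.0)
        window = 0.5 - 0.5 * np.cos(np.pi * window)
    else:
        window = (dist <= radius).astype(float)
    sideband = np.fft.ifft2(spec * window)
    rows = np.arange(holo.intensity.shape[0])[:, None]
    cols = np.arange(holo.intensity.shape[1])[None, :]
    # demodulate the carrier exactly, including fractional-bin components
    demod = np.exp(-2j * np.pi * (carrier[0] * rows + carrier[1] * cols))
    phase = np.angle(sideband * demod)
    return PhaseImage(phase, units=RADIANS, pixel_size_um=holo.pixel_size_um)


def unwrap_phase(wrapped: PhaseImage) -> PhaseImage:
    """Unwrap a phase image to a spatially continuous surface.

    Output differs from the input by integer multiples of 2*pi pointwise.
    """
    if wrapped.units != RADIANS:
        raise ValueError("can only unwrap a phase image in radians")
    unwrapped = np.asarray(_skimage_unwrap(wrapped.values), dtype=float)
    return PhaseImage(
        unwrapped,
        units=RADIANS,
        wavelength_um=wrapped.wavelength_um,
        pixel_size_um=wrapped.pixel_size_um,
    )


def _poly_design(shape: Tuple[int, int], degree: int) -> np.ndarray:
    """Design matrix of 2-D monomials x^i y^j, i + j <= degree, on [-1, 1]^2."""
    rows = np.linspace(-1.0, 1.0, shape[0])[:, None] * np.ones((1, shape[1]))
    cols = np.ones((shape[0], 1)) * np.linspace(-1.0, 1.0, shape[1])[None, :]
    terms = [
        (rows ** i) * (cols ** j)
        for i in range(degree + 1)
        for j in range(degree + 1 - i)
    ]
    return np.stack([t.ravel() for t in terms], axis=1)


def compensate_background(
    phase: PhaseImage,
    degree: int = 2,
    background_mask: Optional[np.ndarray] = None,
) -> PhaseImage:
    """Subtract a least-squares polynomial compensation surface.

    The surface is fitted on cell-free background pixels only: either the
    supplied boolean mask, or pixels below the Otsu threshold of the
    unwrapped phase.
    """
    values = phase.values
    if background_mask is None:
        background_mask = values < threshold_otsu(values)
    background_mask = np.asarray(background_mask, dtype=bool)
    design = _poly_design(values.shape, degree)
    n_coeff = design.shape[1]
    bg = background_mask.ravel()
    if int(bg.sum()) < n_coeff:
        raise InsufficientBackgroundError(
            f"{int(bg.sum())} background pixels for {n_coeff} coefficients"
        )
    coef, *_ = np.linalg.lstsq(design[bg], values.ravel()[bg], rcond=None)
    surface = (design @ coef).reshape(values.shape)
    return PhaseImage(
        values - surface,
        units=phase.units,
        wavelength_um=phase.wavelength_um,
        pixel_size_um=phase.pixel_size_um,
    )


def phase_to_dry_mass(
    phase: PhaseImage,
    wavelength_um: Optional[float] = None,
    gamma_ml_per_g: float = DEFAULT_GAMMA_ML_PER_G,
) -> PhaseImage:
    """Convert phase (radians) to dry-mass surface density (pg/um^2).

    rho = lambda * phi / (2 * pi * gamma), with 1 ml/g = 1 um^3/pg so the
    result carries pg/um^2 directly.
    """
    if phase.units != RADIANS:
        raise ValueError("input must be a phase image in radians")
    lam = wavelength_um if wavelength_um is not None else phase.wavelength_um
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    if gamma_ml_per_g <= 0:
        raise ValueError("refraction increment must be positive")
    rho = lam * phase.values / (2.0 * np.pi * gamma_ml_per_g)
    return PhaseImage(
        rho,
        units=PG_PER_UM2,
        wavelength_um=lam,
        pixel_size_um=phase.pixel_size_um,
    )


def dry_mass_to_phase(
    density: np.ndarray,
    wavelength_um: float = DEFAULT_WAVELENGTH_UM,
    gamma_ml_per_g: float = DEFAULT_GAMMA_ML_PER_G,
) -> np.ndarray:
    """Inverse of :func:`phase_to_dry_mass` on raw arrays (forward model)."""
    if wavelength_um <= 0 or gamma_ml_per_g <= 0:
        raise ValueError("wavelength and refraction increment must be positive")
    return 2.0 * np.pi * gamma_ml_per_g * np.asarray(density, dtype=float) / wavelength_um
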