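"""In-plane fibre orientations from 2D microscopy.

Two estimators are provided:

* :func:`fit_pli_sinusoid` — polarised light imaging (PLI).  As the analyser
  is rotated through 180 degrees the transmitted intensity of birefringent
  myelin follows

      I(rho) = (I_T / 2) [1 + sin(delta) sin(2 (rho - phi))]

  where phi is the in-plane fibre direction, |sin delta| the retardance and
  I_T the transmittance.  On an equally spaced rotation series the second
  harmonic of the discrete Fourier transform recovers phi exactly for
  noiseless model data.

* :func:`structure_tensor_orientations` — stained histology.  The smoothed
  outer product of Gaussian-derivative image gradients yields a 2x2 tensor
  per pixel whose minor eigenvector is the local texture (fibre) direction;
  (lam1 - lam2) / (lam1 + lam2) measures orientation coherence.

Both emit angles in [0, pi) in the row-towards-column image convention,
which maps onto the plane frame's u/v axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import PlaneFrame

__all__ = [
    "PliStack",
    "PliFitResult",
    "StructureTensorResult",
    "InPlaneAngleMap",
    "fit_pli_sinusoid",
    "structure_tensor_orientations",
    "to_inplane_map",
]

#: retardance below this is treated as orientation-free background
RETARDANCE_FLOOR = 1e-6
#: structure-tensor coherence below this is treated as isotropic
COHERENCE_FLOOR = 0.01


@dataclass
class PliStack:
    """Rotation series of PLI intensity images.

    ``intensities`` has shape (n_rotations, rows, cols); ``analyser_angles``
    are degrees, strictly increasing and equally spaced on [0, 180).
    """

    intensities: np.ndarray
    analyser_angles: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.analyser_angles = np.asarray(self.analyser_angles, dtype=float)
        ang = self.analyser_angles
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (n_rotations, rows, cols)")
        if len(ang) != self.intensities.shape[0]:
            raise ValueError("angle count must match stack depth")
        if len(ang) < 3:
            raise ValueError("at least 3 analyser rotations are required")
        if np.any(ang < 0) or np.any(ang >= 180):
            raise ValueError("analyser angles must lie in [0, 180)")
        steps = np.diff(ang)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-6:
            raise ValueError("analyser angles must be strictly increasing and equally spaced")


@dataclass
class PliFitResult:
    """Per-pixel sinusoid fit: phase (rad, [0, pi)), retardance, transmittance."""

    phase: np.ndarray
    retardance: np.ndarray
    transmittance: np.ndarray
    valid_mask: np.ndarray


@dataclass
class StructureTensorResult:
    angle: np.ndarray
    coherence: np.ndarray
    valid_mask: np.ndarray


@dataclass
class InPlaneAngleMap:
    """In-plane fibre angle per microscopy pixel, with geometry metadata."""

    angle: np.ndarray
    valid_mask: np.ndarray
    pixel_size: tuple[float, float]
    plane_frame: PlaneFrame = field(default_factory=PlaneFrame.axis_aligned)

    def __post_init__(self):
        self.angle = np.asarray(self.angle, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.angle.shape != self.valid_mask.shape:
            raise ValueError("angle and mask shapes differ")
        if min(self.pixel_size) <= 0:
            raise ValueError("pixel sizes must be positive")


def fit_pli_sinusoid(
    stack: PliStack,
    phase_offset_deg: float = 0.0,
    flat_field: np.ndarray | None = None,
    retardance_floor: float = RETARDANCE_FLOOR,
) -> PliFitResult:
    """Fit the PLI sinusoid per pixel via the second-harmonic DFT component.

    ``phase_offset_deg`` accommodates instruments whose extinction convention
    puts minima at fibre-parallel rather than fibre-perpendicular analyser
    angles (a 90-degree offset); ``flat_field`` optionally divides out a
    background illumination image before fitting.
    """
    I = stack.intensities
    if flat_field is not None:
        I = I / np.asarray(flat_field, dtype=float)
    rho = np.deg2rad(stack.analyser_angles)
    n = len(rho)
    mean = I.mean(axis=0)
    # complex second-harmonic component; uniform spacing over a half turn
    z = np.tensordot(np.exp(-2j * rho), I, axes=(0, 0)) / n
    amplitude = 2.0 * np.abs(z)
    # I = m + a sin(2 rho - 2 phi)  =>  z = (a / 2) exp(-i (2 phi + pi/2))
    phase = (-np.angle(z) - np.pi / 2) / 2.0 + np.deg2rad(phase_offset_deg)
    phase = np.mod(phase, np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        retardance = np.where(mean > 0, amplitude / mean, 0.0)
    retardance = np.clip(retardance, 0.0, 1.0)
    transmittance = 2.0 * mean
    valid = (transmittance > 0) & (retardance > retardance_floor)
    return PliFitResult(phase, retardance, transmittance, valid)


def structure_tensor_orientations(
    image: np.ndarray,
    sigma_gradient: float = 1.0,
    sigma_smooth: float = 10.0,
    coherence_floor: float = COHERENCE_FLOOR,
) -> StructureTensorResult:
    """Fibre orientation and coherence from the 2D structure tensor.

    Gradients are Gaussian derivatives at scale ``sigma_gradient``; the
    gradient outer products are smoothed at ``sigma_smooth``.  The reported
    angle is the minor-eigenvector orientation (perpendicular to the dominant
    gradient), i.e. along the image texture.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2D and at least 3x3")
    if sigma_gradient <= 0 or sigma_smooth <= 0:
        raise ValueError("sigmas must be positive")
    gr = gaussian_filter(img, sigma_gradient, order=(1, 0))
    gc = gaussian_filter(img, sigma_gradient, order=(0, 1))
    Jrr = gaussian_filter(gr * gr, sigma_smooth)
    Jrc = gaussian_filter(gr * gc, sigma_smooth)
    Jcc = gaussian_filter(gc * gc, sigma_smooth)
    # orientation of the major eigenvector (dominant gradient)
    theta_max = 0.5 * np.arctan2(2 * Jrc, Jrr - Jcc)
    angle = np.mod(theta_max + np.pi / 2, np.pi)
    trace = Jrr + Jcc
    diff = np.sqrt((Jrr - Jcc) ** 2 + 4 * Jrc**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(trace > 0, diff / trace, 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    valid = coherence >= coherence_floor
    return StructureTensorResult(angle, coherence, valid)


def to_inplane_map(
    source: PliFitResult | StructureTensorResult,
    pixel_size: tuple[float, float],
    plane_frame: PlaneFrame,
) -> InPlaneAngleMap:
    """Package an estimator result as an :class:`InPlaneAngleMap`."""
    if pixel_size is None or min(pixel_size) <= 0:
        raise ValueError("a positive pixel size is required")
    angle = source.phase if isinstance(source, PliFitResult) else source.angle
    return InPlaneAngleMap(
        angle=np.mod(np.asarray(angle, dtype=float), np.pi),
        valid_mask=np.asarray(source.valid_mask, dtype=bool).copy(),
        pixel_size=tuple(pixel_size),
        plane_frame=plane_frame,
    )
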