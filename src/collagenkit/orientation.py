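"""Structure-tensor orientation and coherency of fibrillar collagen images.

The local organisation of birefringent collagen in polarised-light
micrographs is summarised by the Gaussian-windowed structure tensor

    J = [[<fx fx>, <fx fy>],
         [<fx fy>, <fy fy>]]

where ``fx``, ``fy`` are intensity gradients and ``< >`` denotes a Gaussian
window average.  Coherency, the eigenvalue contrast (l1 - l2)/(l1 + l2),
ranges from 0 (locally isotropic texture) to 1 (a single dominant local
orientation) and is the standard fibre-alignment statistic produced by
OrientationJ-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["OrientationField", "structure_tensor_field", "mean_coherency"]

#: boundary handling used for every Gaussian convolution in this module
_BOUNDARY_MODE = "nearest"


@dataclass(frozen=True)
class OrientationField:
    """Per-pixel orientation statistics from the structure tensor.

    Attributes
    ----------
    theta:
        Orientation of local *structures* (ridge direction, i.e. the
        eigenvector of the smaller structure-tensor eigenvalue) in degrees,
        in the half-open interval (-90, 90], measured from the image x-axis,
        anticlockwise positive.  NaN where ``energy`` is zero.
    coherency:
        Eigenvalue contrast (l1 - l2)/(l1 + l2) in [0, 1]; zero where the
        tensor vanishes.
    energy:
        Tensor trace l1 + l2 (local gradient energy), nonnegative.
    """

    theta: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where orientation is defined (energy > 0)."""
        return self.energy > 0


def _wrap_orientation_deg(theta: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees into (-90, 90]."""
    wrapped = (np.asarray(theta) + 90.0) % 180.0 - 90.0
    # map the -90 representative onto +90 so the interval is half-open
    return np.where(wrapped == -90.0, 90.0, wrapped)


def structure_tensor_field(
    image: np.ndarray,
    sigma_grad: float = 1.0,
    sigma_window: float = 4.0,
) -> OrientationField:
    """Compute the per-pixel structure-tensor orientation field.

    Parameters
    ----------
    image:
        2-D grayscale intensity grid.
    sigma_grad:
        Gaussian pre-smoothing scale (pixels) applied before centred
        finite-difference gradients.
    sigma_window:
        Gaussian window scale (pixels) over which the gradient outer
        products are averaged; must satisfy ``sigma_window >= sigma_grad``.

    Notes
    -----
    ``theta`` follows the y-up mathematical convention (anticlockwise
    positive from the x-axis) even though image rows increase downwards;
    a horizontal ridge therefore reports 0 deg and a vertical ridge 90 deg.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D grayscale array")
    if not (0 < sigma_grad <= sigma_window):
        raise ValueError("require sigma_window >= sigma_grad > 0")

    smoothed = ndimage.gaussian_filter(image, sigma_grad, mode=_BOUNDARY_MODE)
    # rows are y (down in array space); negate to use y-up convention
    grad_row, grad_col = np.gradient(smoothed)
    fx = grad_col
    fy = -grad_row

    jxx = ndimage.gaussian_filter(fx * fx, sigma_window, mode=_BOUNDARY_MODE)
    jxy = ndimage.gaussian_filter(fx * fy, sigma_window, mode=_BOUNDARY_MODE)
    jyy = ndimage.gaussian_filter(fy * fy, sigma_window, mode=_BOUNDARY_MODE)

    energy = jxx + jyy
    # eigenvalue gap; trace**2 >= gap**2 guarantees coherency <= 1
    gap = np.hypot(jxx - jyy, 2.0 * jxy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(energy > 0, gap / np.where(energy > 0, energy, 1.0), 0.0)
    coherency = np.clip(coherency, 0.0, 1.0)

    # dominant *gradient* orientation, then rotate 90 deg to the structure axis
    theta_grad = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    theta = _wrap_orientation_deg(theta_grad + 90.0)
    theta = np.where(energy > 0, theta, np.nan)

    return OrientationField(theta=theta, coherency=coherency, energy=energy)


def mean_coherency(
    field: OrientationField,
    roi: np.ndarray | None = None,
    energy_quantile: float = 0.1,
) -> float:
    """Energy-gated mean coherency over a region of interest.

    Pixels whose gradient energy is at or below the ``energy_quantile``
    quantile of ROI energies are excluded, so that structureless background
    does not dilute the alignment estimate.

    Raises
    ------
    ValueError
        If the ROI is empty or no pixel passes the energy gate.
    """
    if roi is None:
        roi = np.ones_like(field.energy, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != field.energy.shape:
        raise ValueError("roi shape must match the field")
    if not roi.any():
        raise ValueError("empty ROI")
    if not (0 <= energy_quantile < 1):
        raise ValueError("energy_quantile must lie in [0, 1)")

    energies = field.energy[roi]
    gate = np.quantile(energies, energy_quantile)
    selected = roi & (field.energy > gate) & (field.energy > 0)
    if not selected.any():
        raise ValueError("no pixel passes the energy gate (structureless ROI)")
    return float(field.coherency[selected].mean())


def orientation_overlay(field: OrientationField) -> np.ndarray:
    """Colour-wheel visualisation: hue encodes theta, brightness energy.

    Returns an RGB float array in [0, 1], mirroring the standard
    orientation-map rendering of fibre-alignment figures.
    """
    from skimage.color import hsv2rgb

    theta = np.where(np.isnan(field.theta), 0.0, field.theta)
    hue = (theta + 90.0) / 180.0
    energy = field.energy
    vmax = energy.max()
    value = energy / vmax if vmax > 0 else np.zeros_like(energy)
    hsv = np.stack([hue, field.coherency, value], axis=-1)
    return hsv2rgb(hsv)
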