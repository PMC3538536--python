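"""Detector-domain corrections applied before reconstruction.

Flat/dark normalization, Gaussian smoothing of the projections, ring
artifact suppression in the sinogram domain (per-column bias removal), and
unsharp-mask edge enhancement for reconstructed slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import CorrectionError
from .optics import ProjectionSet

__all__ = [
    "NormalizedSinograms",
    "flat_dark_correct",
    "smooth",
    "ring_correct",
    "edge_enhance",
]

logger = logging.getLogger(__name__)

#: dead-pixel threshold, relative to the flat-field dynamic range
DEAD_PIXEL_EPS = 1e-6


@dataclass
class NormalizedSinograms:
    """Flat/dark-corrected relative transmission frames.

    ``data`` has shape (n_angles, rows, cols); values are typically in
    (0, ~1.2] — phase fringes may locally exceed 1.
    """

    data: np.ndarray
    angles: np.ndarray
    pixel_size_um: float


def flat_dark_correct(raw: ProjectionSet) -> NormalizedSinograms:
    """Normalize raw counts: T = (P - mean(darks)) / (mean(flats) - mean(darks)).

    Pixels whose flat-minus-dark level is below ``DEAD_PIXEL_EPS`` of the
    flat dynamic range are considered dead; their transmission is replaced
    per frame by the median of the valid 3x3 neighbourhood and logged.
    """
    if raw.flats.shape[0] < 1 or raw.darks.shape[0] < 1:
        raise CorrectionError("need at least one flat and one dark frame")
    flat_mean = raw.flats.mean(axis=0)
    dark_mean = raw.darks.mean(axis=0)
    denom = flat_mean - dark_mean
    eps = DEAD_PIXEL_EPS * max(float(denom.max()), 0.0)
    valid = denom > max(eps, 0.0)
    if not valid.any():
        raise CorrectionError("flat field equals dark field everywhere")
    safe = np.where(valid, denom, 1.0)
    data = (raw.projections - dark_mean) / safe
    dead = np.argwhere(~valid)
    if len(dead):
        logger.warning("flat_dark_correct: repairing %d dead pixel(s)", len(dead))
        rows, cols = valid.shape
        for r, c in dead:
            r0, r1 = max(r - 1, 0), min(r + 2, rows)
            c0, c1 = max(c - 1, 0), min(c + 2, cols)
            patch_valid = valid[r0:r1, c0:c1]
            if patch_valid.any():
                patch = data[:, r0:r1, c0:c1]
                data[:, r, c] = np.median(
                    patch.reshape(len(data), -1)[:, patch_valid.ravel()], axis=1
                )
            else:
                data[:, r, c] = 0.0
    return NormalizedSinograms(
        data=data,
        angles=np.asarray(raw.angles, dtype=np.float64),
        pixel_size_um=raw.geometry.pixel_size_um,
    )


def smooth(sinograms: NormalizedSinograms, strength: float) -> NormalizedSinograms:
    """Gaussian smoothing (sigma = ``strength`` pixels) within each frame.

    ``strength`` 0 is the identity.  Noise variance of white noise drops by
    roughly 1 / (4 pi sigma^2).
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        data = sinograms.data.copy()
    else:
        data = ndimage.gaussian_filter(
            sinograms.data, sigma=(0.0, strength, strength), mode="nearest"
        )
    return NormalizedSinograms(data, sinograms.angles.copy(), sinograms.pixel_size_um)


def ring_correct(sinograms: NormalizedSinograms, window: int = 15) -> NormalizedSinograms:
    """Suppress ring artifacts by removing stationary per-column bias.

    For each detector pixel the mean over all angles is compared with a
    median-smoothed trend along the columns; the residual (an angle-
    stationary offset, the signature of a miscalibrated column) is
    subtracted.  The bias field is centred so each projection's spatial
    mean is preserved exactly.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    mean_map = sinograms.data.mean(axis=0)  # (rows, cols)
    trend = ndimage.median_filter(mean_map, size=(1, window), mode="reflect")
    bias = mean_map - trend
    bias -= bias.mean()
    return NormalizedSinograms(
        sinograms.data - bias[None, :, :],
        sinograms.angles.copy(),
        sinograms.pixel_size_um,
    )


def edge_enhance(slice_image: np.ndarray, amount: float, radius: float) -> np.ndarray:
    """Unsharp masking: out = in + amount * (in - Gaussian(in, radius))."""
    if amount < 0:
        raise ValueError("amount must be >= 0")
    img = np.asarray(slice_image, dtype=np.float64)
    if amount == 0 or radius <= 0:
        return img.copy()
    blurred = ndimage.gaussian_filter(img, sigma=radius, mode="nearest")
    return img + amount * (img - blurred)
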