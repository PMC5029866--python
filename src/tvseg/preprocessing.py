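"""RGB-to-grayscale reduction and gradient computation.

H&E-stained histopathology images carry the nucleus/stroma contrast in
their color: hematoxylin stains chromatin dark blue-purple, eosin stains
cytoplasm and stroma pink.  Rather than fixing a color deconvolution
matrix, the pipeline projects each image onto the first principal
component of its own 3x3 RGB channel covariance, which adapts to the
staining level of the slide.  The projection sign is normalized so that
nuclei come out *dark* (low values), because downstream vote weights are
proportional to ``1 - A`` where ``A`` is the grayscale intensity.

Gradients are plain 3x3 Sobel responses; magnitude and two-argument
arctangent orientation feed the stick-voting stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "GradientField",
    "SOBEL_H",
    "SOBEL_V",
    "as_float_rgb",
    "read_rgb",
    "rgb_to_grayscale_pca",
    "compute_gradients",
]

# Horizontal-derivative Sobel kernel (applied by correlation); the
# vertical kernel is its transpose.
SOBEL_H = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_V = SOBEL_H.T.copy()


@dataclass(frozen=True)
class GradientField:
    """Per-pixel Sobel gradient of a grayscale image.

    Attributes
    ----------
    magnitude : (H, W) ndarray
        ``sqrt(gh**2 + gv**2)``, nonnegative.
    direction : (H, W) ndarray
        ``atan2(gv, gh)`` in ``(-pi, pi]``; 0 by convention where the
        magnitude vanishes.
    gh, gv : (H, W) ndarray
        Raw horizontal (d/dcol) and vertical (d/drow) Sobel responses.
    """

    magnitude: np.ndarray
    direction: np.ndarray
    gh: np.ndarray
    gv: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


def as_float_rgb(pixels: np.ndarray) -> np.ndarray:
    """Normalize an (H, W, 3) image to float64 in [0, 1].

    Integer images are divided by their dtype maximum (255 for 8-bit,
    65535 for 16-bit); float images must already lie in [0, 1].
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {pixels.shape}")
    if pixels.shape[0] < 1 or pixels.shape[1] < 1:
        raise ValueError("zero-size image")
    if np.issubdtype(pixels.dtype, np.integer):
        return pixels.astype(np.float64) / np.iinfo(pixels.dtype).max
    out = pixels.astype(np.float64)
    if out.min() < 0.0 or out.max() > 1.0:
        raise ValueError("float RGB input must lie in [0, 1]")
    return out


def read_rgb(path) -> np.ndarray:
    """Read a PNG/TIFF image and return float RGB in [0, 1].

    Grayscale inputs are replicated to 3 channels; an alpha channel, if
    present, is dropped.
    """
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    return as_float_rgb(raw)


def _rescale01(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo == 0.0:
        return values.copy()
    return (values - lo) / (hi - lo)


def rgb_to_grayscale_pca(rgb: np.ndarray) -> np.ndarray:
    """Project RGB pixels onto the first principal component of the
    per-image channel covariance and rescale to [0, 1].

    The sign of the principal axis is arbitrary, so it is fixed by a
    luminance rule: if the darkest-luminance decile of pixels projects
    *higher* than the brightest decile, the projection is negated.  This
    guarantees that hematoxylin-dark nuclei map to low grayscale values.

    A constant-color image has a degenerate covariance; in that case the
    channel mean is returned (with a warning).
    """
    rgb = as_float_rgb(rgb)
    flat = rgb.reshape(-1, 3)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / max(flat.shape[0] - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 1e-15:
        warnings.warn(
            "degenerate channel covariance (constant-color image); "
            "falling back to the channel mean",
            stacklevel=2,
        )
        return flat.mean(axis=1).reshape(rgb.shape[:2])
    proj = centered @ eigvecs[:, -1]

    luminance = flat.mean(axis=1)
    order = np.argsort(luminance, kind="stable")
    decile = max(flat.shape[0] // 10, 1)
    if proj[order[:decile]].mean() > proj[order[-decile:]].mean():
        proj = -proj
    return _rescale01(proj).reshape(rgb.shape[:2])


def compute_gradients(gray: np.ndarray) -> GradientField:
    """Sobel gradient magnitude and orientation of a grayscale image.

    Borders are handled by edge replication.  Orientation uses the
    two-argument arctangent so quadrant information (needed to orient
    voting sticks) is preserved; pixels with zero magnitude get
    orientation 0 by convention.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("grayscale image must be 2-D")
    gh = ndimage.correlate(gray, SOBEL_H, mode="nearest")
    gv = ndimage.correlate(gray, SOBEL_V, mode="nearest")
    # kill float dust so constant regions are exactly flat
    gh[np.abs(gh) < 1e-12] = 0.0
    gv[np.abs(gv) < 1e-12] = 0.0
    magnitude = np.hypot(gh, gv)
    direction = np.where(magnitude > 0.0, np.arctan2(gv, gh), 0.0)
    return GradientField(magnitude=magnitude, direction=direction, gh=gh, gv=gv)
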