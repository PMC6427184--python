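"""Information channels and image (dis)similarity measures.

Three information channels feed the evidence chain: the raw gray image, the
Canny edge map, and the phase-angle reconstruction (inverse Fourier
transform of a unit-magnitude spectrum retaining only the original phase).
Similarity measures: normalized cross-correlation (NCC, Pearson form so the
range is [-1, 1]), mutual information (MI, base-2, equal-width bins over
[0, 1]) and peak signal-to-noise ratio (PSNR, dB against peak 1.0).
"""

from __future__ import annotations

import enum

import numpy as np
from skimage import feature, filters

from .image import as_image

__all__ = [
    "ChannelKind",
    "edge_channel",
    "phase_channel",
    "extract_channel",
    "ncc",
    "mi",
    "mse",
    "psnr",
    "MEASURES",
]


class ChannelKind(enum.Enum):
    GRAY = "gray"
    EDGE = "edge"
    PHASE = "phase"


# Canny defaults: the canonical operator's sigma and relative double
# thresholds; all exposed through configs since no single choice is
# privileged by the registration chain.
CANNY_SIGMA = 1.4142
CANNY_LOW = 0.1
CANNY_HIGH = 0.2


def edge_channel(
    img,
    low_fraction: float = CANNY_LOW,
    high_fraction: float = CANNY_HIGH,
    sigma: float = CANNY_SIGMA,
) -> np.ndarray:
    """Binary Canny edge map with double thresholds relative to the peak gradient.

    Thresholds are `low_fraction` / `high_fraction` of the maximum gradient
    magnitude of the Gaussian-smoothed image.  A constant (gradient-free)
    image yields an all-zero map rather than an error.
    """
    img = as_image(img)
    if not 0.0 <= low_fraction < high_fraction <= 1.0:
        raise ValueError("need 0 <= low_fraction < high_fraction <= 1")
    smoothed = filters.gaussian(img, sigma=sigma, preserve_range=True)
    gmax = float(filters.sobel(smoothed).max())
    if gmax <= 0.0:
        return np.zeros_like(img)
    edges = feature.canny(
        img,
        sigma=sigma,
        low_threshold=low_fraction * gmax,
        high_threshold=high_fraction * gmax,
        use_quantiles=False,
    )
    return edges.astype(np.float64)


def phase_channel(img) -> np.ndarray:
    """Phase-angle reconstruction: unit-magnitude spectrum, original phase.

    The real part of the inverse transform is min-max rescaled to [0, 1];
    the degenerate all-equal case maps to 0.
    """
    img = as_image(img)
    spectrum = np.fft.fft2(img)
    recon = np.real(np.fft.ifft2(np.exp(1j * np.angle(spectrum))))
    lo, hi = recon.min(), recon.max()
    if hi - lo <= 0.0:
        return np.zeros_like(img)
    return (recon - lo) / (hi - lo)


def extract_channel(img, kind: ChannelKind, **kwargs) -> np.ndarray:
    if kind is ChannelKind.GRAY:
        return as_image(img)
    if kind is ChannelKind.EDGE:
        return edge_channel(img, **kwargs)
    if kind is ChannelKind.PHASE:
        return phase_channel(img)
    raise ValueError(f"unknown channel kind {kind!r}")


def _check_pair(a, b, mask=None):
    a, b = as_image(a), as_image(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        sel = np.asarray(mask, bool)
        if sel.shape != a.shape:
            raise ValueError("mask shape must match the images")
        return a[sel], b[sel]
    return a.ravel(), b.ravel()


def ncc(a, b, mask=None) -> float:
    """Normalized cross-correlation (Pearson correlation of intensities).

    Returns 0 by convention when either image is constant (the measure is
    undefined there; an edge map of a featureless region is the typical
    case and must not abort the evidence chain).  An optional boolean mask
    restricts the computation to a pixel subset.
    """
    a, b = _check_pair(a, b, mask)
    if a.size == 0:
        return 0.0
    da = a - a.mean()
    db = b - b.mean()
    sa = np.sqrt(np.mean(da * da))
    sb = np.sqrt(np.mean(db * db))
    if sa == 0.0 or sb == 0.0:
        return 0.0
    value = float(np.mean(da * db) / (sa * sb))
    return float(np.clip(value, -1.0, 1.0))


def _mi_codes(ia: np.ndarray, ib: np.ndarray, bins: int) -> float:
    """MI in bits from pre-binned index vectors (sparse joint histogram)."""
    n = ia.size
    if n == 0:
        return 0.0
    codes, counts = np.unique(ia * bins + ib, return_counts=True)
    pj = counts / n
    pa = np.bincount(ia, minlength=bins) / n
    pb = np.bincount(ib, minlength=bins) / n
    denom = pa[codes // bins] * pb[codes % bins]
    return float(np.sum(pj * np.log2(pj / denom)))


def quantize(img: np.ndarray, bins: int = 256) -> np.ndarray:
    """Equal-width [0, 1] intensity binning to integer indices."""
    return np.minimum((np.asarray(img) * bins).astype(np.intp), bins - 1)


def mi(a, b, bins: int = 256, mask=None) -> float:
    """Mutual information in bits over equal-width intensity bins on [0, 1]."""
    a, b = _check_pair(a, b, mask)
    return _mi_codes(quantize(a, bins), quantize(b, bins), bins)


def mse(a, b, mask=None) -> float:
    a, b = _check_pair(a, b, mask)
    if a.size == 0:
        return 0.0
    d = a - b
    return float(np.mean(d * d))


def psnr(a, b, mask=None) -> float:
    """PSNR in dB with peak 1.0; +inf when the images are identical.

    Identical to the 255-scale 8-bit formula: both peak^2 and the MSE pick
    up the same 255^2 factor under rescaling.
    """
    err = mse(a, b, mask)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / err))


#: similarity measures usable as dense-registration objectives (larger = more similar)
MEASURES = {"ncc": ncc, "mi": mi, "psnr": psnr}
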