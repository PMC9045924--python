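"""Degree-of-polarization maps and image-quality metrics (PSNR, SSIM,
CIEDE2000) with optional region masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray, rgb2lab, deltaE_ciede2000
from skimage.metrics import structural_similarity

from .forward import PolarimetricImagePair

__all__ = ["DOPMap", "MetricReport", "dop", "psnr", "ssim", "ciede2000",
           "evaluate"]

PSNR_CAP_DB = 100.0
MIN_SSIM_SIZE = 11


@dataclass(frozen=True)
class DOPMap:
    """Per-pixel degree of polarization with a validity mask.

    ``valid`` is False where co + cross == 0 (DOP undefined there; such
    pixels are flagged rather than silently zeroed).
    """

    dop: np.ndarray
    valid: np.ndarray

    @property
    def scalar(self) -> np.ndarray:
        """Channel-averaged HxW map (identity if already 2-D)."""
        return self.dop.mean(axis=2) if self.dop.ndim == 3 else self.dop


@dataclass(frozen=True)
class MetricReport:
    psnr: float
    ssim: float
    ciede2000: float
    dop_psnr: float | None = None
    dop_ssim: float | None = None
    dop_ciede2000: float | None = None

    def as_dict(self) -> dict:
        out = {"psnr": self.psnr, "ssim": self.ssim,
               "ciede2000": self.ciede2000}
        if self.dop_psnr is not None:
            out.update({"dop_psnr": self.dop_psnr, "dop_ssim": self.dop_ssim,
                        "dop_ciede2000": self.dop_ciede2000})
        return out


def dop(pair: PolarimetricImagePair) -> DOPMap:
    """Two-channel degree of polarization (co-cross)/(co+cross), clamped
    to [0, 1]."""
    total = pair.co + pair.cross
    valid = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(valid, (pair.co - pair.cross) / np.where(valid, total, 1.0),
                     0.0)
    return DOPMap(np.clip(d, 0.0, 1.0), valid)


def _masked(image: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.asarray(image, dtype=float).ravel()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return np.asarray(image, dtype=float)[mask].ravel()


def psnr(reference: np.ndarray, test: np.ndarray,
         mask: np.ndarray | None = None, peak: float = 1.0) -> float:
    """10*log10(peak^2 / MSE) over the masked pixels, capped at 100 dB."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    r = _masked(reference, mask)
    t = _masked(test, mask)
    mse = float(np.mean((r - t) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(peak**2 / mse))


def _bbox(mask: np.ndarray) -> tuple[slice, slice]:
    if mask.ndim == 3:
        mask = mask.any(axis=2)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))


def ssim(reference: np.ndarray, test: np.ndarray,
         mask: np.ndarray | None = None) -> float:
    """Windowed SSIM (11x11 Gaussian, K1=0.01, K2=0.03) on grayscale.

    A mask is applied as the bounding-box crop of its True region (windowed
    statistics are undefined on arbitrary pixel sets).
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    if reference.ndim == 3:
        reference = rgb2gray(reference)
        test = rgb2gray(test)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask selects no pixels")
        sl = _bbox(mask)
        reference, test = reference[sl], test[sl]
    if min(reference.shape) < MIN_SSIM_SIZE:
        raise ValueError("image (or mask crop) smaller than the SSIM window")
    return float(structural_similarity(
        reference, test, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, data_range=1.0))


def ciede2000(reference: np.ndarray, test: np.ndarray,
              mask: np.ndarray | None = None) -> float:
    """Mean per-pixel CIEDE2000 color difference (sRGB in [0,1], D65)."""
    reference = np.clip(np.asarray(reference, dtype=float), 0.0, 1.0)
    test = np.clip(np.asarray(test, dtype=float), 0.0, 1.0)
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    if reference.ndim == 2:
        reference = np.repeat(reference[..., None], 3, axis=2)
        test = np.repeat(test[..., None], 3, axis=2)
    de = deltaE_ciede2000(rgb2lab(reference), rgb2lab(test))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 3:
            mask = mask.any(axis=2)
        de = _masked(de, mask)
    return float(np.mean(de))


def evaluate(reference: np.ndarray, test: np.ndarray,
             pair_reference: PolarimetricImagePair | None = None,
             pair_test: PolarimetricImagePair | None = None,
             mask: np.ndarray | None = None) -> MetricReport:
    """PSNR/SSIM/CIEDE2000 of an image pair and (optionally) of the DOP maps
    of two polarimetric pairs."""
    report = {
        "psnr": psnr(reference, test, mask),
        "ssim": ssim(reference, test, mask),
        "ciede2000": ciede2000(reference, test, mask),
    }
    if pair_reference is not None and pair_test is not None:
        dref = dop(pair_reference).dop
        dtest = dop(pair_test).dop
        report.update({
            "dop_psnr": psnr(dref, dtest, mask),
            "dop_ssim": ssim(dref, dtest, mask),
            "dop_ciede2000": ciede2000(dref, dtest, mask),
        })
    return MetricReport(**report)
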