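"""Image and config I/O plus run-provenance sidecars.

Images are exchanged as linear radiance in [0, 1] (no gamma decode by
default; the capture chain is assumed linear).  PNG covers 8-bit output;
TIFF covers 16-bit integer and 32-bit float maps.  8- and 16-bit PNG/TIFF
of 1 or 3 channels are readable.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["read_image", "write_image", "read_polarimetric_stack",
           "write_provenance", "srgb_decode"]

_DTYPE_MAX = {np.dtype("uint8"): 255.0, np.dtype("uint16"): 65535.0}


def srgb_decode(image: np.ndarray) -> np.ndarray:
    """Inverse sRGB companding to linear radiance."""
    a = 0.055
    return np.where(image <= 0.04045, image / 12.92,
                    ((image + a) / (1 + a)) ** 2.4)


def read_image(path, srgb: bool = False) -> np.ndarray:
    """Read a PNG/TIFF image as HxWx3 radiance in [0, 1].

    8/16-bit integers are normalized by their dtype maximum; float data is
    taken as-is.  Grayscale is replicated to three channels.
    """
    path = Path(path)
    try:
        data = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype in _DTYPE_MAX:
        img = data.astype(float) / _DTYPE_MAX[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        img = data.astype(float)
    else:
        raise IOError(f"unsupported pixel type {data.dtype} in {path}")
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    elif img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    elif img.ndim != 3 or img.shape[2] != 3:
        raise IOError(f"unsupported image layout {data.shape} in {path}")
    if srgb:
        img = srgb_decode(img)
    return img


def write_image(image: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write an image, clamping to [0, 1] before quantization.

    ``bit_depth`` 8 or 16 quantizes (PNG/TIFF); 32 writes float32 TIFF
    losslessly (TIFF only).
    """
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if image.min() < 0.0 or image.max() > 1.0:
        if bit_depth != 32:
            logger.warning("clamping out-of-range values for %s", path)
        image = np.clip(image, 0.0, 1.0) if bit_depth != 32 else image
    try:
        if bit_depth == 8:
            iio.imwrite(path, np.round(image * 255.0).astype(np.uint8))
        elif bit_depth == 16:
            # 16-bit integer output is TIFF-only (PIL cannot encode
            # 48-bit RGB PNG)
            if path.suffix.lower() not in (".tif", ".tiff"):
                raise ValueError("16-bit output requires a TIFF path")
            arr = np.round(image * 65535.0).astype(np.uint16)
            tifffile.imwrite(path, arr,
                             photometric="rgb" if arr.ndim == 3 else
                             "minisblack")
        elif bit_depth == 32:
            if path.suffix.lower() not in (".tif", ".tiff"):
                raise ValueError("32-bit float output requires a TIFF path")
            tifffile.imwrite(path, image.astype(np.float32),
                             photometric="rgb" if image.ndim == 3 else
                             "minisblack")
        else:
            raise ValueError(f"unsupported bit depth {bit_depth}")
    except OSError as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def read_polarimetric_stack(path, srgb: bool = False
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4-page (0/45/90/135 degree) TIFF and return the (0, 90) pages
    as the co/cross pair."""
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read stack {path}: {exc}") from exc
    if pages.ndim < 3 or pages.shape[0] != 4:
        raise IOError(f"expected a 4-page polarimetric stack in {path}")

    def norm(page):
        if page.dtype in _DTYPE_MAX:
            img = page.astype(float) / _DTYPE_MAX[page.dtype]
        else:
            img = page.astype(float)
        if img.ndim == 2:
            img = np.repeat(img[..., None], 3, axis=2)
        return srgb_decode(img) if srgb else img

    return norm(pages[0]), norm(pages[2])


def write_provenance(out_dir, config: dict) -> Path:
    """Drop a machine-readable record of the run beside its outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "tool": "desmoke",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.UTC).isoformat(),
        "config": config,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
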