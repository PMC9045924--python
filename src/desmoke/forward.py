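"""Synthetic-data generator: smoke-free polarimetric scenes degraded by the
two-term scattering model with a spatially varying optical-depth map.

Per pixel, per color channel and per polarization channel the degraded
radiance is ``I = J * exp(-u) + A * (1 - exp(-u))`` where ``u`` is the
dimensionless optical thickness and ``A`` the ambient ("airlight") radiance
of that polarization channel.  All images are linear radiance in [0, 1];
clamping happens only at export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalDepthMap",
    "PolarimetricImagePair",
    "Airlight",
    "generate_scene",
    "generate_optical_depth",
    "degrade",
]


@dataclass(frozen=True)
class OpticalDepthMap:
    """Per-pixel optical thickness u(x) >= 0, shape (H, W) or (H, W, 3)."""

    u: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        if not np.all(np.isfinite(u)) or np.any(u < 0):
            raise ValueError("optical depth must be finite and non-negative")
        object.__setattr__(self, "u", u)

    @property
    def transmission(self) -> np.ndarray:
        return np.exp(-self.u)


@dataclass
class PolarimetricImagePair:
    """Registered co/cross RGB radiance images, shape (H, W, 3)."""

    co: np.ndarray
    cross: np.ndarray
    tag: str = "ground-truth"

    def __post_init__(self):
        self.co = np.asarray(self.co, dtype=float)
        self.cross = np.asarray(self.cross, dtype=float)
        if self.co.shape != self.cross.shape:
            raise ValueError("co and cross images must have the same shape")

    @property
    def total(self) -> np.ndarray:
        return self.co + self.cross


@dataclass(frozen=True)
class Airlight:
    """Ambient radiance at infinite optical depth, per polarization channel."""

    co_rgb: np.ndarray
    cross_rgb: np.ndarray

    def __post_init__(self):
        for name in ("co_rgb", "cross_rgb"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} components must lie in [0, 1]")
            object.__setattr__(self, name, v)


def _checker(height: int, width: int, rng) -> np.ndarray:
    """Color-checker-like patch grid with mild illumination falloff.

    The palette reuses each color on several patches scattered across the
    grid, like the repeated neutral/skin rows of a physical checker chart.
    """
    ny, nx = 6, 8
    colors = rng.uniform(0.08, 0.95, size=(16, 3))
    assignment = rng.permutation(np.arange(ny * nx) % len(colors))
    img = np.zeros((height, width, 3))
    ys = np.linspace(0, height, ny + 1).astype(int)
    xs = np.linspace(0, width, nx + 1).astype(int)
    for i in range(ny):
        for j in range(nx):
            img[ys[i]:ys[i + 1], xs[j]:xs[j + 1]] = colors[
                assignment[i * nx + j]]
    yy, xx = np.mgrid[0:height, 0:width]
    falloff = 1.0 - 0.1 * (((yy / height - 0.5) ** 2
                            + (xx / width - 0.5) ** 2) * 4.0)
    return img * falloff[..., None]


def _blobs(height: int, width: int, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    img = np.full((height, width, 3), 0.15)
    for _ in range(12):
        cy, cx = rng.uniform(0, height), rng.uniform(0, width)
        sig = rng.uniform(0.05, 0.2) * min(height, width)
        color = rng.uniform(0.2, 0.95, size=3)
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        img += bump[..., None] * color
    return np.clip(img / img.max(), 0.02, 1.0)


def _tissue_texture(height: int, width: int, rng) -> np.ndarray:
    base = np.array([0.62, 0.28, 0.24])  # reddish tissue tone
    tex = _multiscale_noise(height, width, rng)
    tex = 0.6 + 0.4 * (tex - tex.min()) / (np.ptp(tex) + 1e-12)
    img = base[None, None, :] * tex[..., None]
    img[..., 1] *= 0.9 + 0.2 * _multiscale_noise(height, width, rng)
    return np.clip(img, 0.02, 1.0)


def _multiscale_noise(height: int, width: int, rng) -> np.ndarray:
    """Sum of bilinearly upsampled white-noise octaves, values ~O(1)."""
    out = np.zeros((height, width))
    amp, total = 1.0, 0.0
    size = 4
    while size <= max(height, width):
        coarse = rng.standard_normal((size, size))
        ys = np.linspace(0, size - 1, height)
        xs = np.linspace(0, size - 1, width)
        y0 = np.clip(ys.astype(int), 0, size - 2)
        x0 = np.clip(xs.astype(int), 0, size - 2)
        fy = (ys - y0)[:, None]
        fx = (xs - x0)[None, :]
        c00 = coarse[np.ix_(y0, x0)]
        c01 = coarse[np.ix_(y0, x0 + 1)]
        c10 = coarse[np.ix_(y0 + 1, x0)]
        c11 = coarse[np.ix_(y0 + 1, x0 + 1)]
        layer = (c00 * (1 - fy) * (1 - fx) + c01 * (1 - fy) * fx
                 + c10 * fy * (1 - fx) + c11 * fy * fx)
        out += amp * layer
        total += amp
        amp *= 0.5
        size *= 2
    return out / total


_SCENES = {"checker": _checker, "blobs": _blobs, "tissue-texture": _tissue_texture}


def generate_scene(kind: str, height: int, width: int, scene_dop: float = 0.0,
                   rng_seed: int = 0, dop_map: np.ndarray | None = None
                   ) -> PolarimetricImagePair:
    """Smoke-free ground-truth pair with a prescribed degree of polarization.

    The total radiance J is split as ``Jco = J*(1+p)/2`` and
    ``Jcro = J*(1-p)/2`` so that the two-channel DOP of the pair equals
    ``scene_dop`` (or the per-pixel ``dop_map``) everywhere.
    """
    if kind not in _SCENES:
        raise ValueError(f"unknown scene kind {kind!r}")
    if height < 16 or width < 16:
        raise ValueError("scene dimensions must be >= 16")
    if dop_map is None:
        if not 0.0 <= scene_dop < 1.0:
            raise ValueError("scene_dop must lie in [0, 1)")
        p = scene_dop
    else:
        p = np.asarray(dop_map, dtype=float)
        if np.any(p < 0) or np.any(p >= 1):
            raise ValueError("dop_map values must lie in [0, 1)")
        p = p[..., None] if p.ndim == 2 else p
    rng = np.random.default_rng(rng_seed)
    j = _SCENES[kind](height, width, rng)
    return PolarimetricImagePair(
        co=j * (1.0 + p) / 2.0, cross=j * (1.0 - p) / 2.0,
        tag="ground-truth",
    )


def generate_optical_depth(kind: str, level: float, height: int, width: int,
                           rng_seed: int = 0) -> OpticalDepthMap:
    """Optical-depth map with spatial mean ~= ``level``.

    ``uniform`` is exactly constant; ``gaussian-blob`` superposes a few
    smooth plumes; ``multiscale-noise`` uses octaves of upsampled noise.
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    if kind == "uniform":
        return OpticalDepthMap(np.full((height, width), float(level)))
    rng = np.random.default_rng(rng_seed)
    if kind == "gaussian-blob":
        yy, xx = np.mgrid[0:height, 0:width]
        u = np.zeros((height, width))
        for _ in range(5):
            cy, cx = rng.uniform(0, height), rng.uniform(0, width)
            sig = rng.uniform(0.15, 0.45) * min(height, width)
            u += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    elif kind == "multiscale-noise":
        u = _multiscale_noise(height, width, rng)
        u = u - u.min()
    else:
        raise ValueError(f"unknown optical depth kind {kind!r}")
    mean = u.mean()
    u = u * (level / mean) if mean > 0 else np.full_like(u, level)
    return OpticalDepthMap(u)


def degrade(truth: PolarimetricImagePair, u: OpticalDepthMap, a: Airlight,
            noise_sigma: float = 0.0, rng_seed: int = 0
            ) -> PolarimetricImagePair:
    """Apply the two-term degradation model to a ground-truth pair."""
    depth = u.u if u.u.ndim == 3 else u.u[..., None]
    if depth.shape[:2] != truth.co.shape[:2]:
        raise ValueError("optical depth and image shapes are inconsistent")
    t = np.exp(-depth)
    co = truth.co * t + a.co_rgb * (1.0 - t)
    cross = truth.cross * t + a.cross_rgb * (1.0 - t)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(rng_seed)
        co = co + rng.normal(0.0, noise_sigma, co.shape)
        cross = cross + rng.normal(0.0, noise_sigma, cross.shape)
    return PolarimetricImagePair(co=co, cross=cross, tag="degraded")
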