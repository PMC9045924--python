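"""Polarization-difference smoke removal.

Stages: per-channel airlight estimation by haze-line Hough voting over
quantized colors, the co-minus-cross polarization difference, per-color
transmission estimation ``t = 1 - (Ico - Icro) / Aco``, and reconstruction
``J = 2*(Icro - Acro)/t + 2*Acro``.  Every pixel is processed independently;
the airlight is a per-channel scalar.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .forward import Airlight, PolarimetricImagePair

logger = logging.getLogger(__name__)

__all__ = [
    "TransmissionMap",
    "HazeLineVote",
    "estimate_airlight",
    "polarization_difference",
    "estimate_transmission",
    "reconstruct",
    "desmoke",
    "DesmokeResult",
]

N_CLUSTERS = 64
CANDIDATE_RES = 64
N_ANGLE_BINS = 90


@dataclass(frozen=True)
class TransmissionMap:
    """Per-pixel, per-color transmission in [t_min, 1]."""

    t: np.ndarray
    t_min: float

    def __post_init__(self):
        if self.t_min <= 0:
            raise ValueError("t_min must be positive")
        t = np.asarray(self.t, dtype=float)
        if np.any(t < self.t_min - 1e-12) or np.any(t > 1.0 + 1e-12):
            raise ValueError("transmission values outside [t_min, 1]")
        object.__setattr__(self, "t", t)


@dataclass
class HazeLineVote:
    """Diagnostic record of one 2-D Hough vote for the airlight."""

    plane: tuple[int, int]
    candidate_grid: np.ndarray
    accumulator: np.ndarray
    winner: tuple[float, float]


def _quantize_colors(image: np.ndarray, seed: int
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index the image to 64 representative colors (k-means, fixed seed).

    Returns cluster centers, per-cluster pixel counts and the flat label
    array over all pixels.
    """
    pixels = image.reshape(-1, 3)
    n_pix = pixels.shape[0]
    if n_pix > 20000:  # deterministic subsample for fitting speed
        idx = np.random.default_rng(seed).choice(n_pix, 20000, replace=False)
        fit_px = pixels[idx]
    else:
        fit_px = pixels
    n_unique = np.unique(np.round(fit_px, 4), axis=0).shape[0]
    k = min(N_CLUSTERS, n_unique)
    km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(fit_px)
    labels = km.predict(pixels)
    counts = np.bincount(labels, minlength=k).astype(float)
    return km.cluster_centers_, counts, labels


def _haze_lines(points2d: np.ndarray, labels: np.ndarray, counts: np.ndarray,
                min_extent: float, min_elongation: float = 8.0
                ) -> list[tuple[float, float, float, float]]:
    """Per-cluster haze-line segments in one 2-D color plane.

    Pixels of a color cluster degraded under varying optical depth trace a
    straight segment toward the airlight, so each sufficiently elongated
    cluster (principal axis >= ``min_extent``, axis ratio >=
    ``min_elongation``) contributes one line.  Clusters mixing several
    scene colors spread in two dimensions and are rejected.

    Returns tuples (strength, normal_a, normal_b, offset).
    """
    lines = []
    total = counts.sum()
    for c in range(counts.size):
        if counts[c] < 8:
            continue
        px = points2d[labels == c]
        center = px.mean(axis=0)
        cov = np.cov((px - center).T)
        evals, evecs = np.linalg.eigh(cov)
        major, minor = np.sqrt(max(evals[1], 0.0)), np.sqrt(max(evals[0], 0.0))
        if 4.0 * major < min_extent:  # segment too short to extrapolate
            continue
        if minor > 0 and major / minor < min_elongation:
            continue
        da, db = evecs[:, 1]
        na, nb = -db, da
        lines.append((counts[c] / total, na, nb,
                      float(center[0] * na + center[1] * nb)))
    return lines


def _vote_plane(points2d: np.ndarray, labels: np.ndarray, counts: np.ndarray,
                vmax: float
                ) -> tuple[tuple[float, float] | None, np.ndarray, np.ndarray]:
    """Two-stage Hough vote for the 2-D airlight position in one color plane.

    Stage 1 extracts haze-line segments from the indexed colors
    (:func:`_haze_lines`); stage 2 votes every line into a candidate grid.
    The winner is the candidate crossed by the largest count-weighted set
    of haze lines — the point of maximum weighted collinearity.  Returns
    ``None`` as winner when fewer than two lines were found (the
    intersection is then undefined).
    """
    axis = np.linspace(0.0, vmax, CANDIDATE_RES)
    ca, cb = np.meshgrid(axis, axis, indexing="ij")
    acc = np.zeros_like(ca)
    cell = axis[1] - axis[0]
    tau = 1.5 * cell
    lines = _haze_lines(points2d, labels, counts, min_extent=4.0 * cell)
    if len(lines) < 2:
        return None, np.stack([ca, cb]), acc
    for strength, na, nb, offset in lines:
        rho_cand = ca * na + cb * nb
        acc[np.abs(rho_cand - offset) < tau] += strength
    win = np.unravel_index(np.argmax(acc), acc.shape)
    winner = (float(ca[win]), float(cb[win]))
    return winner, np.stack([ca, cb]), acc


def estimate_airlight(image: np.ndarray, seed: int = 0,
                      return_votes: bool = False):
    """Haze-line airlight estimate for one RGB radiance image.

    Quantizes the image to 64 colors, projects the cluster centers onto the
    RB, GB and RG planes, Hough-votes for the convergence point of the haze
    lines in each plane, and assembles the RGB airlight from the per-plane
    winners (each channel is the mean of its two plane estimates).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    if np.ptp(image) < 1e-6:
        warnings.warn("near-constant image: airlight set to the mean color")
        a = image.reshape(-1, 3).mean(axis=0)
        return (a, []) if return_votes else a
    centers, counts, labels = _quantize_colors(image, seed)
    if centers.shape[0] < 2 or np.ptp(centers) < 1e-4:
        warnings.warn("degenerate clustering: airlight set to the mean color")
        a = image.reshape(-1, 3).mean(axis=0)
        return (a, []) if return_votes else a
    pixels = image.reshape(-1, 3)
    vmax = 1.1 * float(image.max())
    planes = [(0, 2), (1, 2), (0, 1)]  # RB, GB, RG
    votes = []
    channel_sum = np.zeros(3)
    channel_n = np.zeros(3)
    for i, j in planes:
        winner, grid, acc = _vote_plane(pixels[:, (i, j)], labels, counts,
                                        vmax)
        if winner is None:
            continue
        votes.append(HazeLineVote((i, j), grid, acc, winner))
        channel_sum[i] += winner[0]
        channel_sum[j] += winner[1]
        channel_n[i] += 1
        channel_n[j] += 1
    if np.any(channel_n == 0):
        # no usable haze lines (e.g. spatially uniform smoke): fall back to
        # the mean of the brightest pixels, the classical airlight guess
        warnings.warn("too few haze lines: airlight from brightest quantile")
        lum = pixels.mean(axis=1)
        bright = pixels[lum >= np.quantile(lum, 0.99)]
        airlight = bright.mean(axis=0)
        return (airlight, votes) if return_votes else airlight
    airlight = channel_sum / channel_n
    return (airlight, votes) if return_votes else airlight


def polarization_difference(pair: PolarimetricImagePair) -> np.ndarray:
    """Per-pixel, per-channel Ico - Icro, negatives clamped to zero."""
    if pair.co.shape != pair.cross.shape:
        raise ValueError("co/cross shape mismatch")
    return np.maximum(pair.co - pair.cross, 0.0)


def estimate_transmission(difference: np.ndarray, airlight_co: np.ndarray,
                          t_min: float = 0.05) -> TransmissionMap:
    """Per-color transmission ``t_c = 1 - difference_c / A_co,c``."""
    a = np.asarray(airlight_co, dtype=float).reshape(3)
    if np.any(a <= 0):
        raise ValueError("airlight components must be positive")
    t = 1.0 - np.asarray(difference, dtype=float) / a
    return TransmissionMap(np.clip(t, t_min, 1.0), t_min)


def reconstruct(pair: PolarimetricImagePair, t: TransmissionMap,
                airlight_cross: np.ndarray) -> np.ndarray:
    """Restored image ``J = 2*(Icro - Acro)/t + 2*Acro`` (unclamped)."""
    a = np.asarray(airlight_cross, dtype=float).reshape(3)
    return 2.0 * (pair.cross - a) / t.t + 2.0 * a


@dataclass
class DesmokeResult:
    restored: np.ndarray
    transmission: TransmissionMap
    airlight: Airlight
    difference: np.ndarray
    restored_pair: PolarimetricImagePair = field(default=None)


def desmoke(pair: PolarimetricImagePair, t_min: float = 0.05,
            airlight_co: np.ndarray | None = None,
            airlight_cross: np.ndarray | None = None,
            seed: int = 0) -> DesmokeResult:
    """Full pipeline: airlight -> difference -> transmission -> restoration.

    Also restores each polarization channel separately
    (``Jch = (Ich - Ach)/t + Ach``) so the degree of polarization of the
    restored scene can be evaluated downstream.
    """
    if airlight_co is None:
        logger.info("estimating co-channel airlight")
        airlight_co = estimate_airlight(pair.co, seed=seed)
    if airlight_cross is None:
        logger.info("estimating cross-channel airlight")
        airlight_cross = estimate_airlight(pair.cross, seed=seed)
    airlight_co = np.asarray(airlight_co, dtype=float).reshape(3)
    airlight_cross = np.asarray(airlight_cross, dtype=float).reshape(3)
    difference = polarization_difference(pair)
    tmap = estimate_transmission(difference, airlight_co, t_min)
    restored = reconstruct(pair, tmap, airlight_cross)
    restored_pair = PolarimetricImagePair(
        co=(pair.co - airlight_co) / tmap.t + airlight_co,
        cross=(pair.cross - airlight_cross) / tmap.t + airlight_cross,
        tag="restored",
    )
    return DesmokeResult(
        restored=restored,
        transmission=tmap,
        airlight=Airlight(np.clip(airlight_co, 0, 1),
                          np.clip(airlight_cross, 0, 1)),
        difference=difference,
        restored_pair=restored_pair,
    )
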