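"""Meridian-plane Stokes-vector Monte Carlo for a smoke slab over tissue.

Photons carry a Stokes vector expressed in a local orthonormal frame
(e_par, e_perp, direction) with ``e_par × e_perp = direction``.  Scattering
rotates the frame into the scattering plane, applies the sphere scattering
matrix, and renormalizes so that ``s0 == 1`` (radiance is tracked by a
separate scalar weight).  The tissue below the slab is modeled as a Fresnel
interface followed by a depolarizing Lambertian reflector; detection bins
upward-exiting photons into co/cross accumulators relative to the laboratory
frame of the launch polarization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .mie import MieResult

logger = logging.getLogger(__name__)

__all__ = [
    "StokesVector",
    "PhotonState",
    "LayeredMedium",
    "DetectorGrid",
    "SimulationConfig",
    "PhaseSampler",
    "launch_photon",
    "propagate_step",
    "scatter_photon",
    "tissue_interaction",
    "run_simulation",
]

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 10.0


@dataclass
class StokesVector:
    s0: float = 1.0
    s1: float = 0.0
    s2: float = 0.0
    s3: float = 0.0

    @property
    def degree_of_polarization(self) -> float:
        if self.s0 == 0.0:
            return 0.0
        return math.sqrt(self.s1**2 + self.s2**2 + self.s3**2) / self.s0


@dataclass
class PhotonState:
    """Position/direction in cm; frame vectors orthonormal to direction."""

    x: float
    y: float
    z: float
    ux: float
    uy: float
    uz: float
    # e_par (meridian reference) and e_perp, with e_par x e_perp = direction
    mx: float
    my: float
    mz: float
    nx: float
    ny: float
    nz: float
    stokes: StokesVector
    weight: float = 1.0
    alive: bool = True
    event: str | None = None  # set by propagate_step

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def direction(self) -> np.ndarray:
        return np.array([self.ux, self.uy, self.uz])


@dataclass
class LayeredMedium:
    """Smoke slab of thickness ``smoke_depth`` (cm) above a tissue half-space."""

    smoke_depth: float
    mu_s: float
    mu_a: float
    phase: "PhaseSampler | None" = None
    n_smoke: float = 1.0
    tissue_albedo: float = 0.6
    n_tissue: float = 1.50
    half_extent: float = 12.5  # lateral boundary, cm

    def __post_init__(self):
        if self.mu_s < 0 or self.mu_a < 0:
            raise ValueError("mu_s and mu_a must be non-negative")
        if not 0.0 <= self.tissue_albedo <= 1.0:
            raise ValueError("tissue_albedo must lie in [0, 1]")


@dataclass
class DetectorGrid:
    """Co/cross radiance accumulators on a square grid above the tissue."""

    height: float
    extent: float = 25.0
    bins: int = 100
    co_accumulator: np.ndarray = field(default=None)
    cross_accumulator: np.ndarray = field(default=None)
    tallies: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.co_accumulator is None:
            self.co_accumulator = np.zeros((self.bins, self.bins))
        if self.cross_accumulator is None:
            self.cross_accumulator = np.zeros((self.bins, self.bins))

    def bin_index(self, x: float, y: float) -> tuple[int, int] | None:
        half = self.extent / 2.0
        if not (-half <= x < half and -half <= y < half):
            return None
        scale = self.bins / self.extent
        return int((y + half) * scale), int((x + half) * scale)

    @property
    def total_co(self) -> float:
        return float(self.co_accumulator.sum())

    @property
    def total_cross(self) -> float:
        return float(self.cross_accumulator.sum())

    def central_co(self, radius_bins: int = 2) -> float:
        """Summed co radiance of the central (2r+1)² bins."""
        c = self.bins // 2
        sl = slice(c - radius_bins, c + radius_bins + 1)
        return float(self.co_accumulator[sl, sl].sum())


class PhaseSampler:
    """Tabulated sampler for the sphere scattering matrix of a MieResult.

    Draws the polar angle from its marginal density (∝ S11·sinθ) through an
    inverse-CDF table, then the azimuth from the Stokes-conditioned density
    1 + (S12/S11)(s1·cos2φ + s2·sin2φ) by rejection (envelope ≤ 2).
    """

    def __init__(self, mie: MieResult):
        theta = np.asarray(mie.angle_grid, dtype=float)
        s11 = np.asarray(mie.phase_matrix["s11"], dtype=float)
        if not np.any(s11 > 0):
            raise ValueError("degenerate phase table (all zeros)")
        self.theta = theta
        self.s11 = s11
        self.s12 = np.asarray(mie.phase_matrix["s12"], dtype=float)
        self.s33 = np.asarray(mie.phase_matrix["s33"], dtype=float)
        self.s34 = np.asarray(mie.phase_matrix["s34"], dtype=float)
        pdf = s11 * np.sin(theta)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                               * np.diff(theta))])
        if cdf[-1] <= 0:
            raise ValueError("degenerate phase table (zero integral)")
        self.cdf = cdf / cdf[-1]
        self.anisotropy_g = mie.anisotropy_g

    @classmethod
    def isotropic(cls, n_angles: int = 181) -> "PhaseSampler":
        theta = np.linspace(0.0, np.pi, n_angles)
        flat = np.full(n_angles, 1.0 / (4.0 * np.pi))
        zeros = np.zeros(n_angles)
        mie = MieResult(
            size_parameter=0.0, q_sca=1.0, q_abs=0.0, q_ext=1.0,
            anisotropy_g=0.0, sigma_sca=1.0, angle_grid=theta,
            phase_matrix={"s11": flat, "s12": zeros, "s33": flat,
                          "s34": zeros},
        )
        return cls(mie)

    def sample_theta(self, u: float) -> float:
        return float(np.interp(u, self.cdf, self.theta))

    def matrix_at(self, theta: float) -> tuple[float, float, float, float]:
        i = np.searchsorted(self.theta, theta)
        if i <= 0:
            return self.s11[0], self.s12[0], self.s33[0], self.s34[0]
        if i >= self.theta.size:
            return self.s11[-1], self.s12[-1], self.s33[-1], self.s34[-1]
        t0, t1 = self.theta[i - 1], self.theta[i]
        f = (theta - t0) / (t1 - t0)
        lerp = lambda a: float(a[i - 1] + f * (a[i] - a[i - 1]))
        return lerp(self.s11), lerp(self.s12), lerp(self.s33), lerp(self.s34)


@dataclass
class SimulationConfig:
    n_photons: int
    heights: tuple = (2.0, 4.0, 6.0, 8.0)
    mu_s: float = 0.1737
    mu_a: float = 0.0100
    phase: PhaseSampler | None = None
    n_smoke: float = 1.0
    n_tissue: float = 1.50
    tissue_albedo: float = 0.6
    extent: float = 25.0
    bins: int = 100
    seed: int = 0


def launch_photon(medium: LayeredMedium, rng=None) -> PhotonState:
    """Pencil-beam launch: top-center, straight down, horizontal linear pol."""
    return PhotonState(
        x=0.0, y=0.0, z=medium.smoke_depth,
        ux=0.0, uy=0.0, uz=-1.0,
        mx=1.0, my=0.0, mz=0.0,
        nx=0.0, ny=-1.0, nz=0.0,
        stokes=StokesVector(1.0, 1.0, 0.0, 0.0),
        weight=1.0,
    )


def propagate_step(photon: PhotonState, medium: LayeredMedium, rng) -> PhotonState:
    """Move the photon one free path or to the nearest boundary.

    Sets ``photon.event`` to one of ``scatter``, ``tissue``, ``top``,
    ``side``; on a scatter event the absorbed fraction µa/µt is peeled off
    the weight (recorded by the caller via the returned state).
    """
    if not photon.alive:
        raise ValueError("photon is not alive")
    mu_t = medium.mu_s + medium.mu_a
    if mu_t > 0.0:
        s = -math.log(rng.random()) / mu_t
    else:
        s = math.inf

    # distances to slab boundaries
    d_bound = math.inf
    event = "scatter"
    if photon.uz < 0.0:
        d = photon.z / -photon.uz
        if d < d_bound:
            d_bound, event_b = d, "tissue"
    elif photon.uz > 0.0:
        d = (medium.smoke_depth - photon.z) / photon.uz
        if d < d_bound:
            d_bound, event_b = d, "top"
    if photon.uz == 0.0:
        event_b = "side"
    half = medium.half_extent
    for u, p in ((photon.ux, photon.x), (photon.uy, photon.y)):
        if u > 0.0:
            d = (half - p) / u
        elif u < 0.0:
            d = (-half - p) / u
        else:
            continue
        if d < d_bound:
            d_bound, event_b = d, "side"

    if s < d_bound:
        travel = s
    else:
        travel = d_bound
        event = event_b
    photon.x += photon.ux * travel
    photon.y += photon.uy * travel
    photon.z += photon.uz * travel
    photon.event = event
    return photon


def scatter_photon(photon: PhotonState, phase: PhaseSampler, rng) -> PhotonState:
    """Sample a scattering event and update direction, frame and Stokes."""
    if not photon.alive:
        raise ValueError("photon is not alive")
    st = photon.stokes
    s0 = st.s0 if st.s0 != 0.0 else 1.0
    p1, p2 = st.s1 / s0, st.s2 / s0

    theta = phase.sample_theta(rng.random())
    m11, m12, m33, m34 = phase.matrix_at(theta)
    ratio = m12 / m11 if m11 > 0.0 else 0.0
    amp = math.hypot(p1, p2)
    env = 1.0 + abs(ratio) * amp
    while True:
        phi = 2.0 * math.pi * rng.random()
        val = 1.0 + ratio * (p1 * math.cos(2.0 * phi) + p2 * math.sin(2.0 * phi))
        if rng.random() * env <= val:
            break

    cphi, sphi = math.cos(phi), math.sin(phi)
    c2, s2 = math.cos(2.0 * phi), math.sin(2.0 * phi)
    # rotate Stokes reference into the scattering plane
    r1 = c2 * p1 + s2 * p2
    r2 = -s2 * p1 + c2 * p2
    r3 = st.s3 / s0
    # rotate frame about direction by phi
    mx = cphi * photon.mx + sphi * photon.nx
    my = cphi * photon.my + sphi * photon.ny
    mz = cphi * photon.mz + sphi * photon.nz
    nx = -sphi * photon.mx + cphi * photon.nx
    ny = -sphi * photon.my + cphi * photon.ny
    nz = -sphi * photon.mz + cphi * photon.nz
    # deflect direction by theta within the (direction, e_par) plane
    ct, stt = math.cos(theta), math.sin(theta)
    ux = ct * photon.ux + stt * mx
    uy = ct * photon.uy + stt * my
    uz = ct * photon.uz + stt * mz
    mx2 = ct * mx - stt * photon.ux
    my2 = ct * my - stt * photon.uy
    mz2 = ct * mz - stt * photon.uz
    # renormalize against drift
    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
    photon.ux, photon.uy, photon.uz = ux / norm, uy / norm, uz / norm
    norm = math.sqrt(mx2 * mx2 + my2 * my2 + mz2 * mz2)
    photon.mx, photon.my, photon.mz = mx2 / norm, my2 / norm, mz2 / norm
    # e_perp = direction x e_par keeps the frame right-handed
    photon.nx = photon.uy * photon.mz - photon.uz * photon.my
    photon.ny = photon.uz * photon.mx - photon.ux * photon.mz
    photon.nz = photon.ux * photon.my - photon.uy * photon.mx

    t0 = m11 + m12 * r1
    t1 = m12 + m11 * r1
    t2 = m33 * r2 + m34 * r3
    t3 = -m34 * r2 + m33 * r3
    if t0 <= 0.0:
        # fully crossed analyzer limit; keep bookkeeping sane
        t0 = 1e-300
    photon.stokes = StokesVector(1.0, t1 / t0, t2 / t0, t3 / t0)
    return photon


def _fresnel_unpolarized(cos_i: float, n1: float, n2: float) -> float:
    sin_t = n1 / n2 * math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def tissue_interaction(photon: PhotonState, medium: LayeredMedium, rng) -> PhotonState:
    """Fresnel specular pre-step, then depolarizing Lambertian re-emission.

    The photon must be at the tissue surface moving downward.  With
    probability of the unpolarized Fresnel reflectance it reflects
    specularly; otherwise it enters the tissue and is re-emitted upward with
    a cosine-weighted direction and a fully depolarized Stokes vector with
    probability ``tissue_albedo``, or terminated.
    """
    if photon.uz >= 0.0:
        raise ValueError("photon must be moving downward at the tissue surface")
    cos_i = -photon.uz
    refl = _fresnel_unpolarized(cos_i, medium.n_smoke, medium.n_tissue)
    if rng.random() < refl:
        photon.uz = -photon.uz
        photon.mz = -photon.mz
        # rebuild e_perp; mirror reflection flips chirality
        photon.nx = photon.uy * photon.mz - photon.uz * photon.my
        photon.ny = photon.uz * photon.mx - photon.ux * photon.mz
        photon.nz = photon.ux * photon.my - photon.uy * photon.mx
        st = photon.stokes
        photon.stokes = StokesVector(st.s0, st.s1, -st.s2, -st.s3)
        photon.z = 0.0
        return photon
    if rng.random() < medium.tissue_albedo:
        uz = math.sqrt(rng.random())  # cosine-weighted zenith
        phi = 2.0 * math.pi * rng.random()
        sin_z = math.sqrt(max(0.0, 1.0 - uz * uz))
        photon.ux = sin_z * math.cos(phi)
        photon.uy = sin_z * math.sin(phi)
        photon.uz = uz
        # meridian frame for the new direction
        if sin_z > 1e-12:
            photon.mx = uz * math.cos(phi)
            photon.my = uz * math.sin(phi)
            photon.mz = -sin_z
        else:
            photon.mx, photon.my, photon.mz = 1.0, 0.0, 0.0
        photon.nx = photon.uy * photon.mz - photon.uz * photon.my
        photon.ny = photon.uz * photon.mx - photon.ux * photon.mz
        photon.nz = photon.ux * photon.my - photon.uy * photon.mx
        photon.stokes = StokesVector(1.0, 0.0, 0.0, 0.0)
        photon.z = 0.0
        return photon
    photon.alive = False
    photon.event = "tissue_absorbed"
    return photon


def _detect(photon: PhotonState, grid: DetectorGrid) -> bool:
    """Rotate the Stokes vector into the lab frame and bin co/cross."""
    idx = grid.bin_index(photon.x, photon.y)
    if idx is None:
        return False
    d_ex = photon.ux
    px = 1.0 - d_ex * photon.ux
    py = -d_ex * photon.uy
    pz = -d_ex * photon.uz
    norm = math.sqrt(px * px + py * py + pz * pz)
    px, py, pz = px / norm, py / norm, pz / norm
    cos_a = px * photon.mx + py * photon.my + pz * photon.mz
    sin_a = px * photon.nx + py * photon.ny + pz * photon.nz
    c2 = cos_a * cos_a - sin_a * sin_a
    s2 = 2.0 * cos_a * sin_a
    st = photon.stokes
    s0 = st.s0 if st.s0 != 0.0 else 1.0
    s1_lab = (c2 * st.s1 + s2 * st.s2) / s0
    s1_lab = max(-1.0, min(1.0, s1_lab))
    w = photon.weight
    grid.co_accumulator[idx] += w * (1.0 + s1_lab) / 2.0
    grid.cross_accumulator[idx] += w * (1.0 - s1_lab) / 2.0
    return True


def _trace(photon: PhotonState, medium: LayeredMedium, grid: DetectorGrid,
           tallies: dict, rng) -> None:
    mu_t = medium.mu_s + medium.mu_a
    albedo = medium.mu_s / mu_t if mu_t > 0 else 1.0
    while photon.alive:
        propagate_step(photon, medium, rng)
        ev = photon.event
        if ev == "scatter":
            tallies["absorbed"] += photon.weight * (1.0 - albedo)
            photon.weight *= albedo
            scatter_photon(photon, medium.phase, rng)
            if photon.weight < ROULETTE_THRESHOLD:
                if rng.random() < 1.0 / ROULETTE_SURVIVAL:
                    tallies["roulette_net"] -= photon.weight * (
                        ROULETTE_SURVIVAL - 1.0)
                    photon.weight *= ROULETTE_SURVIVAL
                else:
                    tallies["roulette_net"] += photon.weight
                    photon.alive = False
        elif ev == "tissue":
            tissue_interaction(photon, medium, rng)
            if not photon.alive:
                tallies["tissue_absorbed"] += photon.weight
        elif ev == "top":
            if _detect(photon, grid):
                tallies["detected"] += photon.weight
            else:
                tallies["side_escape"] += photon.weight
            photon.alive = False
        elif ev == "side":
            tallies["side_escape"] += photon.weight
            photon.alive = False
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unknown event {ev!r}")


def run_simulation(config: SimulationConfig) -> list[DetectorGrid]:
    """Run one simulation per detector height (slab depth == height).

    Each photon gets a counter-based substream of the master seed, so runs
    are bit-identical for a fixed configuration.
    """
    if config.phase is None:
        raise ValueError("config.phase (a PhaseSampler) is required")
    grids: list[DetectorGrid] = []
    if config.n_photons <= 0:
        logger.warning("zero photons requested; returning empty grids")
    for hi, height in enumerate(config.heights):
        medium = LayeredMedium(
            smoke_depth=height, mu_s=config.mu_s, mu_a=config.mu_a,
            phase=config.phase, n_smoke=config.n_smoke,
            tissue_albedo=config.tissue_albedo, n_tissue=config.n_tissue,
            half_extent=config.extent / 2.0,
        )
        grid = DetectorGrid(height=height, extent=config.extent,
                            bins=config.bins)
        tallies = {
            "launched": 0.0, "detected": 0.0, "absorbed": 0.0,
            "tissue_absorbed": 0.0, "side_escape": 0.0, "roulette_net": 0.0,
        }
        for i in range(config.n_photons):
            rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence(entropy=config.seed,
                                       spawn_key=(hi, i))))
            photon = launch_photon(medium, rng)
            tallies["launched"] += photon.weight
            _trace(photon, medium, grid, tallies, rng)
        grid.tallies = tallies
        grids.append(grid)
    return grids
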