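"""Mie scattering for homogeneous spheres: efficiencies, anisotropy and
phase-matrix tables, for mono- and polydisperse particle populations.

The series is evaluated with the standard logarithmic-derivative downward
recurrence and truncated at the Wiscombe criterion.  Angular tables hold the
four independent scattering-matrix elements of a sphere (S11, S12, S33, S34)
on a uniform grid in scattering angle; S11 is normalized so that its integral
over the full sphere equals one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MieResult",
    "SizeDistribution",
    "compute_mie",
    "scattering_coefficient",
    "gaussian_size_distribution",
    "polydisperse_mie",
]


class MieComputationError(RuntimeError):
    """Raised when the partial-wave series fails to behave."""


@dataclass(frozen=True)
class MieResult:
    """Scattering properties of a (possibly effective) sphere population.

    Attributes
    ----------
    size_parameter : float
        ``pi * diameter * n_medium / wavelength`` (mean diameter for a
        polydisperse result).
    q_sca, q_abs, q_ext : float
        Dimensionless efficiencies, ``q_ext == q_sca + q_abs``.
    anisotropy_g : float
        Mean cosine of the scattering angle.
    sigma_sca : float
        Scattering cross-section in µm².
    angle_grid : ndarray
        Scattering angles in radians, ascending, spanning [0, pi].
    phase_matrix : dict[str, ndarray]
        Keys ``s11``, ``s12``, ``s33``, ``s34``; ``s11`` integrates to 1
        over the sphere (``2*pi*trapz(s11*sin(theta)) == 1``).
    """

    size_parameter: float
    q_sca: float
    q_abs: float
    q_ext: float
    anisotropy_g: float
    sigma_sca: float
    angle_grid: np.ndarray
    phase_matrix: dict

    def export_phase_table(self, path, element: str = "s11") -> None:
        """Write a two-column (angle_deg, value) plain-text table."""
        table = np.column_stack(
            [np.degrees(self.angle_grid), self.phase_matrix[element]]
        )
        np.savetxt(path, table, header=f"angle_deg {element}")


@dataclass(frozen=True)
class SizeDistribution:
    """Discretized number-fraction distribution over sphere diameters (µm)."""

    mean_diameter: float
    coefficient_of_variation: float
    diameters: np.ndarray
    weights: np.ndarray

    @property
    def n_points(self) -> int:
        return self.diameters.size


def _mie_coefficients(x: float, m: complex) -> tuple[np.ndarray, np.ndarray]:
    """Partial-wave coefficients a_n, b_n (n = 1..nmax, Wiscombe cutoff)."""
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x

    # log-derivative D_n(mx), downward from well above the cutoff
    nstart = max(nmax, int(abs(mx))) + 16
    d = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    n = np.arange(1, nmax + 1)
    # Riccati-Bessel psi, chi by upward recurrence (real argument)
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_nm1, psi_n = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_nm1, chi_n = -np.sin(x), np.cos(x)  # chi_{-1}, chi_0
    for k in range(1, nmax + 1):
        psi_np1 = (2 * k - 1) / x * psi_n - psi_nm1
        chi_np1 = (2 * k - 1) / x * chi_n - chi_nm1
        psi[k - 1] = psi_np1
        chi[k - 1] = chi_np1
        psi_nm1, psi_n = psi_n, psi_np1
        chi_nm1, chi_n = chi_n, chi_np1
    psi_prev = np.empty(nmax)
    chi_prev = np.empty(nmax)
    psi_prev[0], chi_prev[0] = np.sin(x), np.cos(x)
    psi_prev[1:], chi_prev[1:] = psi[: nmax - 1], chi[: nmax - 1]
    psi = psi[:nmax]
    chi = chi[:nmax]
    xi = psi - 1j * chi
    xi_prev = psi_prev - 1j * chi_prev

    dn = d[1 : nmax + 1]
    fa = dn / m + n / x
    fb = dn * m + n / x
    a = (fa * psi - psi_prev) / (fa * xi - xi_prev)
    b = (fb * psi - psi_prev) / (fb * xi - xi_prev)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise MieComputationError(
            f"Mie series failed to converge ({nmax} terms, x={x:g})"
        )
    return a, b


def _angular_functions(mu: np.ndarray, nmax: int) -> tuple[np.ndarray, np.ndarray]:
    """pi_n(mu), tau_n(mu) for n = 1..nmax; shape (nmax, len(mu))."""
    pi = np.zeros((nmax + 1, mu.size))
    tau = np.zeros((nmax, mu.size))
    pi[1] = 1.0
    for n in range(1, nmax):
        pi[n + 1] = ((2 * n + 1) * mu * pi[n] - (n + 1) * pi[n - 1]) / n
    for n in range(1, nmax + 1):
        tau[n - 1] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau


def compute_mie(
    diameter: float,
    wavelength: float,
    particle_index: complex,
    medium_index: float = 1.0,
    n_angles: int = 1801,
) -> MieResult:
    """Full Mie solution for a single sphere.

    Parameters are in µm (diameter, vacuum wavelength); ``particle_index`` is
    the complex refractive index of the sphere, ``medium_index`` the real
    index of the host (default air).  ``n_angles`` sets the angular
    resolution of the phase-matrix tables.
    """
    if diameter <= 0 or wavelength <= 0:
        raise ValueError("diameter and wavelength must be positive")
    if medium_index < 1.0:
        raise ValueError("medium_index must be >= 1")
    if n_angles < 2:
        raise ValueError("n_angles must be >= 2")

    x = np.pi * diameter * medium_index / wavelength
    m = complex(particle_index) / medium_index
    a, b = _mie_coefficients(x, m)
    nmax = a.size
    n = np.arange(1, nmax + 1)

    c = 2 * n + 1
    q_sca = (2.0 / x**2) * np.sum(c * (np.abs(a) ** 2 + np.abs(b) ** 2))
    q_ext = (2.0 / x**2) * np.sum(c * (a.real + b.real))
    g_num = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    ) + np.sum(c / (n * (n + 1)) * (a * np.conj(b)).real)
    g = (4.0 / x**2) * g_num / q_sca

    theta = np.linspace(0.0, np.pi, n_angles)
    mu = np.cos(theta)
    pi_n, tau_n = _angular_functions(mu, nmax)
    w = (c / (n * (n + 1)))[:, None]
    s1 = np.sum(w * (a[:, None] * pi_n + b[:, None] * tau_n), axis=0)
    s2 = np.sum(w * (a[:, None] * tau_n + b[:, None] * pi_n), axis=0)

    s11 = 0.5 * (np.abs(s2) ** 2 + np.abs(s1) ** 2)
    s12 = 0.5 * (np.abs(s2) ** 2 - np.abs(s1) ** 2)
    s33 = (s2 * np.conj(s1)).real
    s34 = (s2 * np.conj(s1)).imag
    norm = 2.0 * np.pi * np.trapezoid(s11 * np.sin(theta), theta)
    if norm <= 0:
        raise MieComputationError("degenerate phase function")
    phase = {k: v / norm for k, v in
             {"s11": s11, "s12": s12, "s33": s33, "s34": s34}.items()}

    radius = 0.5 * diameter
    sigma_sca = q_sca * np.pi * radius**2
    return MieResult(
        size_parameter=float(x),
        q_sca=float(q_sca),
        q_abs=float(q_ext - q_sca),
        q_ext=float(q_ext),
        anisotropy_g=float(g),
        sigma_sca=float(sigma_sca),
        angle_grid=theta,
        phase_matrix=phase,
    )


def scattering_coefficient(result: MieResult, number_density: float) -> float:
    """Scattering coefficient in cm⁻¹ for ``number_density`` particles/µm³."""
    if number_density < 0:
        raise ValueError("number_density must be non-negative")
    # µm⁻¹ -> cm⁻¹
    return number_density * result.sigma_sca * 1.0e4


def gaussian_size_distribution(
    mean_diameter: float, cv: float, n_points: int
) -> SizeDistribution:
    """Truncated Gaussian number distribution over diameters.

    The grid spans mean ± 4 standard deviations, floored at
    ``max(mean - 4*sd, mean/100)`` so all diameters stay positive; weights
    follow the Gaussian density and are renormalized to sum to one.
    """
    if mean_diameter <= 0:
        raise ValueError("mean_diameter must be positive")
    if not 0.0 <= cv < 1.0:
        raise ValueError("coefficient of variation must lie in [0, 1)")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if cv == 0.0 or n_points == 1:
        return SizeDistribution(
            mean_diameter, cv, np.array([mean_diameter]), np.array([1.0])
        )
    sd = cv * mean_diameter
    lo = max(mean_diameter - 4.0 * sd, mean_diameter / 100.0)
    hi = mean_diameter + 4.0 * sd
    diam = np.linspace(lo, hi, n_points)
    w = np.exp(-0.5 * ((diam - mean_diameter) / sd) ** 2)
    w /= w.sum()
    return SizeDistribution(mean_diameter, cv, diam, w)


def polydisperse_mie(
    dist: SizeDistribution,
    wavelength: float,
    particle_index: complex,
    medium_index: float = 1.0,
    n_angles: int = 1801,
) -> MieResult:
    """Effective Mie properties of a polydisperse population.

    Efficiencies and the cross-section are number-weighted means; the
    anisotropy and the normalized phase matrix are weighted by each size's
    contribution to scattering (weight × cross-section), the radiative
    transfer convention for mixing phase functions.
    """
    singles = [
        compute_mie(d, wavelength, particle_index, medium_index, n_angles)
        for d in dist.diameters
    ]
    w = dist.weights
    sigma = np.array([r.sigma_sca for r in singles])
    sca_w = w * sigma
    sca_norm = sca_w.sum()
    if sca_norm <= 0:
        raise MieComputationError("population has zero scattering")
    sca_w = sca_w / sca_norm

    q_sca = float(np.sum(w * [r.q_sca for r in singles]))
    q_ext = float(np.sum(w * [r.q_ext for r in singles]))
    g = float(np.sum(sca_w * [r.anisotropy_g for r in singles]))
    theta = singles[0].angle_grid
    phase = {
        k: np.sum(
            sca_w[:, None] * np.stack([r.phase_matrix[k] for r in singles]),
            axis=0,
        )
        for k in ("s11", "s12", "s33", "s34")
    }
    x_mean = np.pi * dist.mean_diameter * medium_index / wavelength
    return MieResult(
        size_parameter=float(x_mean),
        q_sca=q_sca,
        q_abs=float(q_ext - q_sca),
        q_ext=q_ext,
        anisotropy_g=g,
        sigma_sca=float(np.sum(w * sigma)),
        angle_grid=theta,
        phase_matrix=phase,
    )
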