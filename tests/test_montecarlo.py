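import math

import numpy as np
import pytest
from scipy import stats

from desmoke.montecarlo import (
    DetectorGrid,
    LayeredMedium,
    PhaseSampler,
    PhotonState,
    SimulationConfig,
    StokesVector,
    launch_photon,
    propagate_step,
    run_simulation,
    scatter_photon,
    tissue_interaction,
)

from .conftest import MU_A


@pytest.fixture(scope="module")
def phase_large(mie_large):
    return PhaseSampler(mie_large)


@pytest.fixture(scope="module")
def phase_iso():
    return PhaseSampler.isotropic()


def medium(depth=2.0, mu_s=0.6205, mu_a=MU_A, phase=None, albedo=0.6,
           n_smoke=1.0):
    return LayeredMedium(smoke_depth=depth, mu_s=mu_s, mu_a=mu_a,
                         phase=phase, tissue_albedo=albedo, n_smoke=n_smoke)


class TestLaunch:
    def test_launch_state(self):
        p = launch_photon(medium(depth=3.0))
        np.testing.assert_allclose(p.position, [0.0, 0.0, 3.0])
        np.testing.assert_allclose(p.direction, [0.0, 0.0, -1.0])
        assert (p.stokes.s0, p.stokes.s1, p.stokes.s2, p.stokes.s3) == \
            (1.0, 1.0, 0.0, 0.0)

    def test_launch_weight_is_one(self):
        assert launch_photon(medium()).weight == 1.0

    def test_deterministic(self):
        a = launch_photon(medium(), np.random.default_rng(7))
        b = launch_photon(medium(), np.random.default_rng(7))
        assert a == b

    def test_frame_orthonormal(self):
        p = launch_photon(medium())
        d = p.direction
        m = np.array([p.mx, p.my, p.mz])
        n = np.array([p.nx, p.ny, p.nz])
        np.testing.assert_allclose(np.cross(m, n), d, atol=1e-12)
        assert abs(np.dot(m, d)) < 1e-12 and abs(np.dot(n, d)) < 1e-12


class TestPropagate:
    def test_vacuum_slab_ballistic(self, rng):
        med = medium(depth=5.0, mu_s=0.0, mu_a=0.0)
        p = launch_photon(med)
        propagate_step(p, med, rng)
        assert p.event == "tissue"
        assert p.z == pytest.approx(0.0, abs=1e-12)
        assert p.weight == 1.0

    def test_free_path_mean(self, rng):
        mu_t = 0.1737 + MU_A  # Table 1 small-particle medium
        med = medium(depth=1e9, mu_s=0.1737, mu_a=MU_A)
        n = 100_000
        paths = np.empty(n)
        for i in range(n):
            p = launch_photon(med)
            z0 = p.z
            propagate_step(p, med, rng)
            paths[i] = z0 - p.z
        expected = 1.0 / mu_t
        se = expected / math.sqrt(n)  # exponential: sd == mean
        assert abs(paths.mean() - expected) < 2 * se

    def test_albedo_weight_after_scatter(self, phase_iso, rng):
        med = medium(depth=1e9, mu_s=0.1737, mu_a=0.0100, phase=phase_iso)
        p = launch_photon(med)
        while True:
            propagate_step(p, med, rng)
            if p.event == "scatter":
                break
        p.weight *= med.mu_s / (med.mu_s + med.mu_a)
        assert p.weight == pytest.approx(0.1737 / 0.1837, rel=1e-12)
        assert p.weight == pytest.approx(0.9456, abs=5e-5)

    def test_dead_photon_rejected(self, rng):
        p = launch_photon(medium())
        p.alive = False
        with pytest.raises(ValueError):
            propagate_step(p, medium(), rng)


class TestScatter:
    def test_isotropic_cos_theta_uniform(self, phase_iso, rng):
        n = 100_000
        cos = np.empty(n)
        med = medium(phase=phase_iso)
        for i in range(n):
            p = launch_photon(med)
            p.stokes = StokesVector(1, 0, 0, 0)
            d0 = p.direction
            scatter_photon(p, phase_iso, rng)
            cos[i] = float(d0 @ p.direction)
        counts, _ = np.histogram(cos, bins=20, range=(-1, 1))
        chi2, p_val = stats.chisquare(counts)
        assert p_val > 0.001

    def test_mie_mean_cos_matches_g(self, phase_large, mie_large, rng):
        n = 100_000
        acc = 0.0
        med = medium(phase=phase_large)
        for i in range(n):
            p = launch_photon(med)
            p.stokes = StokesVector(1, 0, 0, 0)
            d0 = (p.ux, p.uy, p.uz)
            scatter_photon(p, phase_large, rng)
            acc += d0[0] * p.ux + d0[1] * p.uy + d0[2] * p.uz
        mean = acc / n
        se = math.sqrt(1.0 - mie_large.anisotropy_g**2) / math.sqrt(n)
        assert abs(mean - mie_large.anisotropy_g) < 3 * se
        # the table value itself, within the same sampling tolerance
        assert mean == pytest.approx(0.7324, abs=0.01)

    def test_dop_bounded_and_frame_valid(self, phase_large, rng):
        med = medium(phase=phase_large)
        p = launch_photon(med)
        for _ in range(50):
            scatter_photon(p, phase_large, rng)
            st = p.stokes
            assert st.degree_of_polarization <= 1.0 + 1e-9
            d = p.direction
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-9)
            m = np.array([p.mx, p.my, p.mz])
            n_v = np.array([p.nx, p.ny, p.nz])
            np.testing.assert_allclose(np.cross(m, n_v), d, atol=1e-9)

    def test_zero_rotation_identity(self):
        # rotating the polarization reference by zero leaves Stokes alone
        c2, s2 = math.cos(0.0), math.sin(0.0)
        s1, s2_ = 0.3, -0.4
        assert (c2 * s1 + s2 * s2_, -s2 * s1 + c2 * s2_) == (s1, s2_)

    def test_degenerate_phase_rejected(self, mie_large):
        import dataclasses
        zeros = {k: np.zeros_like(v)
                 for k, v in mie_large.phase_matrix.items()}
        broken = dataclasses.replace(mie_large, phase_matrix=zeros)
        with pytest.raises(ValueError):
            PhaseSampler(broken)


class TestTissue:
    def test_lambertian_mean_cosine(self, rng):
        # index-matched interface so the Fresnel pre-step never fires and
        # every photon is re-emitted diffusely
        med = medium(albedo=1.0, n_smoke=1.5)
        n = 100_000
        acc = 0.0
        for i in range(n):
            p = launch_photon(med)
            p.z = 0.0
            tissue_interaction(p, med, rng)
            assert p.alive
            acc += p.uz
        # cosine-weighted hemisphere: E[cos] = 2/3, sd = sqrt(1/2-4/9)
        se = math.sqrt(0.5 - 4.0 / 9.0) / math.sqrt(n)
        assert abs(acc / n - 2.0 / 3.0) < 2 * se

    def test_fresnel_normal_incidence(self, rng):
        med = medium(albedo=0.0)
        n = 100_000
        reflected = 0
        for i in range(n):
            p = launch_photon(med)
            p.z = 0.0
            tissue_interaction(p, med, rng)
            reflected += p.alive
        expected = ((1.5 - 1.0) / (1.5 + 1.0)) ** 2
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(reflected / n - expected) < 2 * se

    def test_reemitted_fully_depolarized(self, rng):
        med = medium(albedo=1.0)
        for _ in range(100):
            p = launch_photon(med)
            p.z = 0.0
            tissue_interaction(p, med, rng)
            if p.uz > 0 and p.stokes.s1 == 0.0:
                assert p.stokes.degree_of_polarization == 0.0

    def test_upward_photon_rejected(self, rng):
        med = medium()
        p = launch_photon(med)
        p.uz = 1.0
        with pytest.raises(ValueError):
            tissue_interaction(p, med, rng)


class TestRunSimulation:
    def test_co_dominates_small_particles(self, mie_small):
        cfg = SimulationConfig(n_photons=5000, heights=(2.0,), mu_s=0.1737,
                               mu_a=MU_A, phase=PhaseSampler(mie_small),
                               seed=11)
        grid = run_simulation(cfg)[0]
        assert grid.total_co > grid.total_cross

    def test_conservation(self, phase_large):
        cfg = SimulationConfig(n_photons=2000, heights=(4.0,), mu_s=0.6205,
                               mu_a=MU_A, phase=phase_large, seed=5)
        grid = run_simulation(cfg)[0]
        t = grid.tallies
        total = (t["detected"] + t["absorbed"] + t["tissue_absorbed"]
                 + t["side_escape"] + t["roulette_net"])
        assert total == pytest.approx(t["launched"], rel=1e-6)

    def test_determinism_bit_identical(self, phase_large):
        cfg = SimulationConfig(n_photons=500, heights=(2.0,), mu_s=0.6205,
                               mu_a=MU_A, phase=phase_large, seed=42)
        a = run_simulation(cfg)[0]
        b = run_simulation(cfg)[0]
        assert np.array_equal(a.co_accumulator, b.co_accumulator)
        assert np.array_equal(a.cross_accumulator, b.cross_accumulator)

    def test_vacuum_lambertian_depolarized(self, phase_iso):
        # index-matched tissue: the return is purely diffuse and depolarized
        cfg = SimulationConfig(n_photons=20_000, heights=(2.0,), mu_s=0.0,
                               mu_a=0.0, phase=phase_iso, tissue_albedo=1.0,
                               n_smoke=1.5, seed=9)
        grid = run_simulation(cfg)[0]
        co, cross = grid.total_co, grid.total_cross
        assert co + cross > 0
        se = math.sqrt(co + cross)  # unit-weight counting bound
        assert abs(co - cross) < 2 * se

    def test_channel_difference_shrinks_with_depth(self, phase_large):
        # deeper slabs: the central co-minus-cross radiance difference
        # decreases as multiple scattering randomizes the polarization
        cfg = SimulationConfig(n_photons=20_000, heights=(2.0, 4.0, 8.0),
                               mu_s=0.6205, mu_a=MU_A, phase=phase_large,
                               seed=2)
        grids = run_simulation(cfg)
        diffs = []
        for g in grids:
            c = g.bins // 2
            sl = slice(c - 2, c + 3)
            co = g.co_accumulator[sl, sl].sum()
            cross = g.cross_accumulator[sl, sl].sum()
            diffs.append((co - cross, 2.0 * math.sqrt(co + cross)))
        assert diffs[0][0] > 0
        assert diffs[1][0] <= diffs[0][0] + diffs[0][1]
        assert diffs[2][0] <= diffs[1][0] + diffs[1][1]
        assert diffs[2][0] < diffs[0][0]

    def test_albedo_limit_total_reflectance(self, phase_iso):
        # semi-infinite non-absorbing isotropic slab over a perfect
        # Lambertian floor: everything must come back out the top
        cfg = SimulationConfig(n_photons=2000, heights=(6.0,), mu_s=2.0,
                               mu_a=0.0, phase=phase_iso, tissue_albedo=1.0,
                               extent=1e6, bins=10, seed=3)
        grid = run_simulation(cfg)[0]
        t = grid.tallies
        reflectance = t["detected"] / t["launched"]
        assert reflectance > 0.99 or (
            t["detected"] + t["roulette_net"]) / t["launched"] > 0.99

    def test_zero_photons_warns(self, phase_iso, caplog):
        import logging
        cfg = SimulationConfig(n_photons=0, heights=(2.0,), phase=phase_iso)
        with caplog.at_level(logging.WARNING):
            grids = run_simulation(cfg)
        assert grids[0].total_co == 0.0
        assert any("zero photons" in r.message for r in caplog.records)


def test_medium_validation():
    with pytest.raises(ValueError):
        LayeredMedium(smoke_depth=1.0, mu_s=-1.0, mu_a=0.0)
    with pytest.raises(ValueError):
        LayeredMedium(smoke_depth=1.0, mu_s=1.0, mu_a=0.0,
                      tissue_albedo=1.5)


def test_detector_binning():
    grid = DetectorGrid(height=2.0)
    assert grid.bin_index(0.0, 0.0) == (50, 50)
    assert grid.bin_index(-12.5, -12.5) == (0, 0)
    assert grid.bin_index(13.0, 0.0) is None
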