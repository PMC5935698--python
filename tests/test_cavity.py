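"""Cavity-shell model: trend polynomials, shell averaging, Boltzmann
radial averaging, and the consistency of the factorization."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

import xecavity as x
from xecavity.pairfunctions import KB_KCAL_MOL_K, DomainError


class TestTrendModels:
    def test_coordination_number_values(self):
        assert x.eval_Z(x.Z_TREND_MD, 260.56) == pytest.approx(21.989)
        assert round(x.eval_Z(x.Z_TREND_MD, 368.0), 1) == 20.5
        assert round(x.eval_Z(x.Z_TREND_MD, 278.0), 1) == 22.0

    def test_cavity_radius_values(self):
        assert x.eval_R(x.R_TREND_MD, 292.34) == pytest.approx(4.2675)
        # direct arithmetic: 4.2675 + 3.57311e-6 * (368 - 292.34)^2
        assert x.eval_R(x.R_TREND_MD, 368.0) == pytest.approx(4.287954, abs=1e-5)

    def test_cavity_radius_parabola_symmetry(self):
        g = x.R_TREND_MD
        for dx in (1.0, 17.3, 60.0):
            assert x.eval_R(g, g.t_min + dx) == pytest.approx(
                x.eval_R(g, g.t_min - dx)
            )

    def test_surface_density_vertices(self):
        assert x.eval_surface_density(x.DENSITY_D2O, 266.975) == pytest.approx(
            0.0959701
        )
        assert x.eval_surface_density(x.DENSITY_H2O, 270.387) == pytest.approx(
            0.0985138
        )
        # direct arithmetic at 311 K with the H2O parameters
        assert x.eval_surface_density(x.DENSITY_H2O, 311.0) == pytest.approx(
            0.0971460, abs=1e-6
        )

    def test_surface_density_validity_error(self):
        with pytest.raises(x.ModelValidityError):
            x.eval_surface_density(x.DENSITY_H2O, 800.0)

    def test_density_from_structure(self):
        rho = x.surface_density_from_structure(21.989, 4.2675)
        assert rho == pytest.approx(0.09609, abs=1e-5)
        # consistent with the calibrated D2O density at its vertex to 0.2%
        assert rho == pytest.approx(0.0959701, rel=2e-3)
        assert x.surface_density_from_structure(4 * np.pi, 1.0) == pytest.approx(1.0)
        assert x.surface_density_from_structure(0.0, 2.0) == 0.0

    def test_structural_density_consistency_over_range(self):
        """Z(T)/(4 pi R(T)^2) tracks the calibrated D2O density to <0.5%."""
        T = np.linspace(278.0, 368.0, 91)
        implied = x.eval_Z(x.Z_TREND_MD, T) / (
            4.0 * np.pi * x.eval_R(x.R_TREND_MD, T) ** 2
        )
        ref = x.eval_surface_density(x.DENSITY_D2O, T)
        assert np.max(np.abs(implied - ref) / ref) < 0.005


class TestShellAverage:
    def test_zero_offset_returns_point_value(self):
        assert x.shell_average(lambda u: u**2, 4.0, 0.0) == pytest.approx(16.0)
        assert x.shell_average_power(3, 4.0, 0.0) == pytest.approx(4.0**-3)

    def test_constant_integrand_is_normalized(self):
        assert x.shell_average(lambda u: 7.5, 4.0, 2.3) == pytest.approx(7.5)

    def test_inverse_cube_closed_form(self):
        # (1/(2*4*2)) * int_2^6 u^-2 du = 1/48
        assert x.shell_average_power(3, 4.0, 2.0) == pytest.approx(1.0 / 48.0)

    @pytest.mark.parametrize("E", [1, 2, 3, 6, 12, 17])
    @pytest.mark.parametrize("r_frac", [0.1, 0.5, 0.9])
    def test_closed_forms_match_adaptive_quadrature(self, E, r_frac):
        R = 4.1423
        r = r_frac * R
        closed = x.shell_average_power(E, R, r)
        adaptive = x.shell_average(lambda u: u ** (-float(E)), R, r, rtol=1e-11)
        assert closed == pytest.approx(adaptive, rel=1e-8)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            x.shell_average_power(3, 4.0, 4.0)
        with pytest.raises(DomainError):
            x.shell_average(lambda u: u, 4.0, 5.0)


def _mc_boltzmann_oracle(bundle, T, rng, n_samples=8000):
    """Independent Monte-Carlo route to the Boltzmann radial average:
    rejection-sample the Xe offset r against exp(-U(r)/kT) r^2 (with U
    from adaptive quadrature of the pair potential) and average S(r)."""
    R, Z, _ = bundle.structure_at(T)
    pot = bundle.potential

    def logw(r):
        v, _ = quad(lambda u: pot(u) * u, R - r, R + r, epsrel=1e-10, limit=200)
        return -Z * (v / (2.0 * R * r)) / (KB_KCAL_MOL_K * T)

    coarse = np.linspace(1e-6, R * (1 - 1e-9), 600)
    logf_c = np.array([logw(r) for r in coarse]) + 2.0 * np.log(coarse)
    keep = logf_c > logf_c.max() - 34.5
    lo = max(coarse[keep].min() - 0.02, 1e-6)
    hi = min(coarse[keep].max() + 0.02, R * (1 - 1e-9))
    fine = np.linspace(lo, hi, 2500)
    logf = np.array([logw(r) for r in fine]) + 2.0 * np.log(fine)
    logf -= logf.max() + 0.05  # margin keeps the spline below 0
    spl = CubicSpline(fine, logf)
    samples: list[float] = []
    rounds = 0
    while len(samples) < n_samples:
        r = rng.uniform(lo, hi, 20000)
        acc = rng.random(20000) < np.exp(np.maximum(spl(r), -745.0))
        samples.extend(r[acc])
        rounds += 1
        assert rounds < 2000, "rejection acceptance collapsed"
    arr = np.array(samples[:n_samples])
    S = Z * x.shell_average_shift(bundle.shift_function, R, arr)
    return float(S.mean()), float(S.std(ddof=1) / np.sqrt(len(S)))


class TestBoltzmannShift:
    def test_factorization_is_definitional(self):
        res = x.boltzmann_shift(x.CavityModelBundle.fte("H2O"), 311.0)
        assert res.delta == pytest.approx(res.rhoS * res.K_factor, rel=1e-12)

    def test_gauss_matches_adaptive_reference(self):
        b = x.CavityModelBundle.fte("D2O")
        for T in (278.0, 320.0, 368.0):
            g = x.boltzmann_shift(b, T).delta
            a = x.boltzmann_shift(b, T, method="adaptive").delta
            assert g == pytest.approx(a, rel=1e-8)

    def test_zero_potential_constant_shell_average(self):
        """A 1/d pair shift has a constant shell average (D/R for every
        interior position), so with a vanishing potential the Boltzmann
        average must reduce to exactly Z * D / R at every temperature,
        and a sweep of the bundle is flat."""
        zero_pot = x.PairPotential(
            form="tabulated", table=((1e-6, 0.0), (100.0, 0.0))
        )
        f = x.PairShiftFunction(((250.0, 1),))
        R, Z = 4.2, 18.0
        b = x.CavityModelBundle(
            shift_function=f,
            potential=zero_pot,
            geometry=x.CavityGeometry.constant(R),
            coordination=x.CoordinationModel(Z, 0.0, 300.0),
        )
        expected = Z * 250.0 / R
        for T in (250.0, 300.0, 380.0):
            assert x.boltzmann_shift(b, T).delta == pytest.approx(
                expected, rel=1e-10
            )

    def test_quadrature_agrees_with_monte_carlo_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            r0 = rng.uniform(3.9, 4.4)
            eps = rng.uniform(0.8, 2.5)
            d1 = 10.0 ** rng.uniform(7.5, 8.5)
            d2 = -d1 * rng.uniform(50.0, 150.0)
            bundle = x.CavityModelBundle(
                shift_function=x.PairShiftFunction(((d1, 12), (d2, 17))),
                potential=x.PairPotential(r0=r0, epsilon=eps),
                geometry=x.CavityGeometry.constant(rng.uniform(3.9, 4.6)),
                coordination=x.CoordinationModel(rng.uniform(16, 24), 0.0, 300.0),
            )
            T = rng.uniform(260.0, 390.0)
            delta = x.boltzmann_shift(bundle, T).delta
            mc, sem = _mc_boltzmann_oracle(bundle, T, rng)
            assert abs(delta - mc) < 3.0 * sem

    def test_invalid_temperature(self):
        with pytest.raises(DomainError):
            x.boltzmann_shift(x.CavityModelBundle.fte(), -5.0)


class TestTemperatureSweep:
    def test_single_point_equals_direct_call(self):
        b = x.CavityModelBundle.fte("H2O")
        sweep = x.temperature_sweep(b, [311.0])
        direct = x.boltzmann_shift(b, 311.0)
        assert sweep[0].delta == direct.delta

    def test_order_preserved(self):
        b = x.CavityModelBundle.fte("H2O")
        temps = [320.0, 280.0, 300.0]
        out = x.temperature_sweep(b, temps)
        assert [r.T for r in out] == temps

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            x.temperature_sweep(x.CavityModelBundle.fte(), [])

    def test_failure_names_temperature(self):
        b = x.CavityModelBundle.fte("H2O")
        with pytest.raises(RuntimeError, match="-10"):
            x.temperature_sweep(b, [300.0, -10.0])


class TestFittedBundleShape:
    """Qualitative behaviour of the calibrated model curve."""

    def test_interior_maximum_in_liquid_range(self, fte_solution):
        sweep = x.temperature_sweep(
            fte_solution.bundle("H2O"), np.arange(278.0, 368.1, 1.0)
        )
        d = np.array([r.delta for r in sweep])
        signs = np.sign(np.diff(d))
        assert signs[0] > 0 and signs[-1] < 0  # rises then falls

    def test_maximum_lies_above_density_peak(self, fte_solution):
        t_at_max, _ = x.curve_maximum(fte_solution.bundle("H2O"), 273.0, 360.0)
        assert t_at_max >= fte_solution.density_h2o.t_max

    def test_linear_density_still_produces_maximum(self):
        """Replacing the quadratic surface density by a gently decaying
        linear one (30% loss over 278-5000 K, shallow enough to start
        below the collision factor's low-end slope) still yields an
        interior shift maximum — far above any liquid range."""
        from xecavity.cavity import _ShellEngine

        b = x.CavityModelBundle.fte("D2O")
        R = b.geometry.r0
        eng = _ShellEngine(b.shift_function, b.potential, R, 256, 64)
        area = 4.0 * np.pi * R * R
        rho278 = x.eval_surface_density(b.density, 278.0)
        T = np.linspace(278.0, 5000.0, 400)
        rho = rho278 * (1.0 - 0.3 * (T - 278.0) / (5000.0 - 278.0))
        delta = np.array([eng.delta(t, z) for t, z in zip(T, rho * area)])
        k = int(np.argmax(delta))
        assert 0 < k < len(T) - 1
        assert T[k] > 400.0  # outside any liquid range
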