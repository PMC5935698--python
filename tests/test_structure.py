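"""RDF, first-shell statistics and structural trend fits."""

import numpy as np
import pytest

import xecavity as x
from xecavity.pairfunctions import DomainError
from xecavity.structure import FitError, StructureError


def _config_from_oxygens(oxygens, box=None, temperature=300.0, ref_density=None):
    oxygens = np.asarray(oxygens, dtype=float)
    hydrogens = np.stack(
        [oxygens + [0.6, 0.6, 0.0], oxygens + [-0.6, 0.6, 0.0]], axis=1
    )
    return x.SolventConfiguration(
        xe=np.zeros(3),
        oxygens=oxygens,
        hydrogens=hydrogens,
        box=box,
        temperature=temperature,
        ref_density=ref_density,
    )


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(3)
        box = 14.0
        configs = [
            _config_from_oxygens(rng.uniform(0, box, (300, 3)), box=box)
            for _ in range(40)
        ]
        r = x.compute_rdf(configs, bin_width=0.25)
        # ignore the innermost bins where expected counts are tiny
        sel = r.bin_centers > 2.0
        assert np.all(np.abs(r.g[sel] - 1.0) < 0.35)
        assert abs(r.g[sel].mean() - 1.0) < 0.02

    def test_single_oxygen_bin_placement(self):
        c = _config_from_oxygens([[3.02, 0.0, 0.0]], ref_density=0.01)
        r = x.compute_rdf([c], bin_width=0.05, max_radius=5.0)
        hit = np.nonzero(r.g > 0)[0]
        assert len(hit) == 1
        assert 3.00 <= r.bin_centers[hit[0]] <= 3.05

    def test_synthetic_shell_peak_location(self):
        rng = np.random.default_rng(7)
        configs = [
            x.gen_configuration(14, 4.0, 0.2, rng, temperature=300.0)
            for _ in range(200)
        ]
        r = x.compute_rdf(configs, bin_width=0.05, max_radius=6.0)
        peak = r.bin_centers[int(np.argmax(r.g))]
        assert abs(peak - 4.0) <= 0.1

    def test_periodic_max_radius_guard(self):
        c = _config_from_oxygens([[3.0, 0.0, 0.0]], box=10.0)
        with pytest.raises(DomainError):
            x.compute_rdf([c], max_radius=8.0)

    def test_mixed_temperatures_rejected(self):
        a = _config_from_oxygens([[3.0, 0, 0]], temperature=280.0, ref_density=0.01)
        b = _config_from_oxygens([[3.0, 0, 0]], temperature=290.0, ref_density=0.01)
        with pytest.raises(ValueError):
            x.compute_rdf([a, b])

    def test_normalization_counts_recovered(self):
        """Integrating g * 4 pi d^2 rho over the histogram recovers the
        mean number of oxygens within the cutoff (periodic case)."""
        rng = np.random.default_rng(9)
        box = 12.0
        configs = [
            _config_from_oxygens(rng.uniform(0, box, (150, 3)), box=box)
            for _ in range(25)
        ]
        r = x.compute_rdf(configs, bin_width=0.1)
        rho = 150 / box**3
        integral = np.sum(r.g * 4 * np.pi * r.bin_centers**2 * rho * r.bin_width)
        counts = [
            np.count_nonzero(x.xe_oxygen_distances(c) <= r.bin_centers[-1] + 0.05)
            for c in configs
        ]
        assert integral == pytest.approx(np.mean(counts), rel=0.05)


class TestFirstMinimum:
    def test_double_gaussian_minimum_between_peaks(self):
        d = np.arange(0.025, 9.0, 0.05)
        # two equal Gaussian peaks at 4.2 and 6.8; the minimum between
        # them falls exactly midway, at 5.5
        g = (
            1.0
            + 2.0 * np.exp(-((d - 4.2) ** 2) / (2 * 0.3**2))
            + 2.0 * np.exp(-((d - 6.8) ** 2) / (2 * 0.3**2))
        )
        r1 = x.find_first_minimum(
            x.RDFResult(bin_centers=d, g=g, bin_width=0.05)
        )
        assert abs(r1 - 5.5) <= 0.05

    def test_monotone_rdf_has_no_minimum(self):
        d = np.arange(0.025, 5.0, 0.05)
        r = x.RDFResult(bin_centers=d, g=np.linspace(0, 3, len(d)), bin_width=0.05)
        with pytest.raises(StructureError):
            x.find_first_minimum(r)

    def test_flat_rdf_has_no_peak(self):
        d = np.arange(0.025, 5.0, 0.05)
        r = x.RDFResult(bin_centers=d, g=np.full(len(d), 0.5), bin_width=0.05)
        with pytest.raises(StructureError):
            x.find_first_minimum(r)

    def test_isolated_shell_minimum_beyond_spread(self):
        rng = np.random.default_rng(21)
        configs = [
            x.gen_configuration(14, 4.0, 0.2, rng, temperature=300.0)
            for _ in range(200)
        ]
        r = x.compute_rdf(configs, bin_width=0.05, max_radius=6.0)
        r1 = x.find_first_minimum(r)
        assert r1 > 4.0 + 2 * 0.2


class TestShellStatistics:
    def test_coordination_counting(self):
        c = _config_from_oxygens(
            [[3.0, 0, 0], [0, 3.5, 0], [0, 0, 6.0]], ref_density=0.01
        )
        assert x.coordination_number(c, 5.5) == 2
        assert x.coordination_number(c, 2.0) == 0
        with pytest.raises(DomainError):
            x.coordination_number(c, -1.0)

    def test_coordination_monotone_in_radius(self):
        rng = np.random.default_rng(5)
        c = x.gen_configuration(18, 4.2, 0.3, rng)
        counts = [x.coordination_number(c, r1) for r1 in np.linspace(2.0, 7.0, 40)]
        assert np.all(np.diff(counts) >= 0)

    def test_cavity_radius_is_mean_shell_distance(self):
        c = _config_from_oxygens([[4.0, 0, 0], [0, 4.4, 0]], ref_density=0.01)
        assert x.cavity_radius(c, 5.5) == pytest.approx(4.2)
        with pytest.raises(StructureError):
            x.cavity_radius(c, 1.0)

    def test_uniform_shell_distance_exact(self):
        n = 12
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
        oxy = 4.2675 * np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(n)]
        )
        c = _config_from_oxygens(oxy, ref_density=0.01)
        assert x.cavity_radius(c, 5.5) == pytest.approx(4.2675)

    def test_mean_coordination_matches_generator(self):
        """Ensemble built from the coordination trend at 278 K recovers
        the trend value within its standard error."""
        rng = np.random.default_rng(13)
        spec = x.SyntheticSpec(
            seed=13,
            temperatures=(278.0,),
            frames_per_temperature=300,
            z_source=x.Z_TREND_MD,
            r_source=4.27,
        )
        traj = x.gen_trajectory(spec)
        s = x.shell_statistics(traj[278.0], 5.5)
        truth = x.eval_Z(x.Z_TREND_MD, 278.0)  # 21.95
        assert abs(s.z_mean - truth) < 3 * max(s.z_sem, 1e-6)

    def test_mean_radius_matches_generator(self):
        rng = np.random.default_rng(17)
        configs = [
            x.gen_configuration(20, 4.27, 0.25, rng, temperature=300.0)
            for _ in range(150)
        ]
        s = x.shell_statistics(configs, 5.5)
        assert abs(s.r_mean - 4.27) < 2 * s.r_sem + 5e-3


class TestStructuralTrends:
    def test_noiseless_recovery_of_trend_parameters(self):
        T = np.arange(278.0, 369.0, 10.0)
        stats = [
            x.ShellStatistics(
                temperature=t,
                z_mean=x.eval_Z(x.Z_TREND_MD, t),
                z_sem=0.0,
                r_mean=x.eval_R(x.R_TREND_MD, t),
                r_sem=0.0,
                n_frames=1,
            )
            for t in T
        ]
        zm, rm = x.fit_structural_trends(stats)
        assert zm.z0 == pytest.approx(21.989, rel=1e-7)
        assert zm.a_z == pytest.approx(0.000126697, rel=1e-6)
        assert zm.t_max == pytest.approx(260.56, rel=1e-6)
        assert rm.r0 == pytest.approx(4.2675, rel=1e-7)
        assert rm.t_min == pytest.approx(292.34, rel=1e-6)

    def test_constant_data_flagged_unidentifiable(self):
        stats = [
            x.ShellStatistics(t, 20.0, 0.0, 4.2, 0.0, 1)
            for t in (280.0, 300.0, 320.0, 340.0)
        ]
        zm, rm = x.fit_structural_trends(stats)
        assert zm.a_z == 0.0 and np.isnan(zm.t_max)
        assert rm.a_r == 0.0

    def test_degenerate_designs_rejected(self):
        mk = lambda t, z: x.ShellStatistics(t, z, 0.0, 4.2, 0.0, 1)
        with pytest.raises(FitError):
            x.fit_structural_trends([mk(280.0, 21.0), mk(300.0, 21.5)])
        with pytest.raises(FitError):
            x.fit_structural_trends(
                [mk(280.0, 21.0), mk(280.0, 21.2), mk(300.0, 21.5)]
            )

    def test_pipeline_recovery_from_synthetic_trajectory(self, trend_trajectory):
        """Fitted vertex temperature of Z(T) lands within 5 K of the
        generator's trend at 200 frames x 10 temperatures."""
        _, _, (zmodel, rmodel) = trend_trajectory
        assert abs(zmodel.t_max - x.Z_TREND_MD.t_max) < 5.0
        assert zmodel.z0 == pytest.approx(x.Z_TREND_MD.z0, abs=0.15)
        assert rmodel.r0 == pytest.approx(x.R_TREND_MD.r0, abs=0.02)
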