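"""Shared fixtures: experimental-parabola series and the heavier
session-scoped artifacts (calibrated model, synthetic ensembles)."""

import numpy as np
import pytest

import xecavity as x


@pytest.fixture(scope="session")
def exp_grid():
    return np.arange(273.0, 360.1, 3.0)


@pytest.fixture(scope="session")
def h2o_series(exp_grid):
    return x.gen_experimental_series(x.EXPERIMENT_H2O, exp_grid, 0.0, 0, "H2O")


@pytest.fixture(scope="session")
def d2o_series(exp_grid):
    return x.gen_experimental_series(x.EXPERIMENT_D2O, exp_grid, 0.0, 0, "D2O")


@pytest.fixture(scope="session")
def fte_solution(h2o_series, d2o_series):
    """Six-parameter calibration against the noiseless parabolas."""
    return x.fit_fte(h2o_series, d2o_series, seed=1)


@pytest.fixture(scope="session")
def closure_ensemble():
    """Trajectory -> pairwise ensemble shift, for the end-to-end closure."""
    spec = x.SyntheticSpec(
        seed=0,
        frames_per_temperature=400,
        z_source=x.Z_TREND_MD,
        r_source=x.R_TREND_MD,
    )
    traj = x.gen_trajectory(spec)
    configs = [c for frames in traj.values() for c in frames]
    points = x.ensemble_average(configs, x.PairShiftFunction.fte())
    return spec, traj, points


@pytest.fixture(scope="session")
def trend_trajectory():
    """200 frames x 10 temperatures for structural-trend recovery."""
    spec = x.SyntheticSpec(
        seed=11,
        frames_per_temperature=200,
        z_source=x.Z_TREND_MD,
        r_source=x.R_TREND_MD,
    )
    traj = x.gen_trajectory(spec)
    stats = [x.shell_statistics(traj[T], 5.5) for T in sorted(traj)]
    return spec, stats, x.fit_structural_trends(stats)
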