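"""Empirical calibration of the cavity model against experiment.

The cavity model is over-parameterized relative to the two observable
shift curves (H2O and D2O), so the calibration fixes the pair
potential and the D2O surface-density trend and frees six parameters:
the two coefficients D1, D2 of the binary shift function (integer
exponents E1, E2 chosen by a separate scan), a single
temperature-independent cavity radius R shared by the isotopes, and
the three H2O surface-density parameters (rho0, a_S, T_S_max).  The
fixed D2O density anchors the overall scale and breaks the
D-coefficients / density degeneracy.

Because the Boltzmann weight depends only on the pair potential, the
model shift is exactly linear in (D1, D2); the fit exploits this by
variable projection — the two coefficients are solved by linear least
squares inside every evaluation, and the outer trust-region optimizer
sees only the four nonlinear parameters (R and the H2O density
triple).  Several restarts over a small grid of cavity radii guard
against local minima; the best solution by joint RMS wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .cavity import (
    DENSITY_D2O,
    CavityGeometry,
    CavityModelBundle,
    SurfaceDensityModel,
    _ShellEngine,
    eval_surface_density,
    leggauss,
    shell_average_power,
)
from .pairfunctions import KB_KCAL_MOL_K
from .pairfunctions import PairPotential, PairShiftFunction
from .trends import FitError, ShiftSeries, fit_parabola

__all__ = ["FTEParameters", "fit_fte", "scan_exponents", "curve_maximum"]


@dataclass(frozen=True)
class FTEParameters:
    """Result of the six-parameter calibration."""

    d1: float  # ppm Å^e1
    d2: float  # ppm Å^e2
    e1: int
    e2: int
    r: float  # Å, shared cavity radius
    density_h2o: SurfaceDensityModel
    density_d2o: SurfaceDensityModel
    rms: float  # joint residual RMS, ppm
    converged: bool = True

    @property
    def shift_function(self) -> PairShiftFunction:
        return PairShiftFunction(((self.d1, self.e1), (self.d2, self.e2)))

    def bundle(self, isotope: str, potential: PairPotential | None = None) -> CavityModelBundle:
        density = (
            self.density_h2o if isotope.upper() == "H2O" else self.density_d2o
        )
        return CavityModelBundle(
            shift_function=self.shift_function,
            potential=potential or PairPotential(),
            geometry=CavityGeometry.constant(self.r),
            density=density,
        )


def _model_curve(
    engine: _ShellEngine, density: SurfaceDensityModel, T: np.ndarray
) -> np.ndarray:
    """Cavity-model shift on a T grid for a fixed-radius engine."""
    rho = eval_surface_density(density, T)
    Z = np.atleast_1d(rho) * 4.0 * np.pi * engine.R ** 2
    return np.array([engine.delta(t, z) for t, z in zip(np.atleast_1d(T), Z)])


def _radial_grids(
    potential: PairPotential, R: float, exps: tuple[int, ...], n_r: int, n_u: int
):
    """Gauss grids for one radius: per-molecule potential shell average
    ``u1(r)`` and the per-exponent shift-basis shell averages ``P[k, r]``."""
    xr, wr = leggauss(n_r)
    r = 0.5 * R * (xr + 1.0)
    wr = 0.5 * R * wr
    xu, wu = leggauss(n_u)
    lo, hi = R - r, R + r
    mid = 0.5 * (hi + lo)[:, None]
    half = 0.5 * (hi - lo)[:, None]
    u = mid + half * xu[None, :]
    u1 = (potential(u) * u * wu[None, :]).sum(axis=1) * half[:, 0] / (2.0 * R * r)
    P = np.stack([shell_average_power(e, R, r) for e in exps])
    return r, wr, u1, P


def _basis_matrix(r, wr, u1, P, T_arr, Z_arr) -> np.ndarray:
    """Boltzmann-averaged basis: column k is the model curve for a
    unit-coefficient single-term shift function ``d**-E_k``."""
    r2 = r * r
    rows = []
    for T, Z in zip(T_arr, Z_arr):
        w = -(Z * u1) / (KB_KCAL_MOL_K * T)
        w = w - w.max()
        e = np.exp(np.clip(w, -745.0, 0.0))
        den = float(np.sum(wr * e * r2))
        rows.append(Z * (P @ (wr * e * r2)) / den)
    return np.array(rows)


def fit_fte(
    h2o: ShiftSeries,
    d2o: ShiftSeries,
    d2o_density: SurfaceDensityModel = DENSITY_D2O,
    potential: PairPotential | None = None,
    e1: int = 12,
    e2: int = 17,
    *,
    seed: int = 0,
    n_starts: int = 8,
    n_r: int = 160,
    n_u: int = 48,
    initial: "FTEParameters | None" = None,
) -> FTEParameters:
    """Joint six-parameter fit of the cavity model to two shift series.

    Raises :class:`~xecavity.trends.FitError` if no start converges;
    otherwise returns the best solution (``converged`` marks whether
    the winning start satisfied the optimizer's own tolerance).
    """
    if len(h2o) == 0 or len(d2o) == 0:
        raise FitError("both series must be nonempty")
    if e1 == e2:
        raise FitError("exponents must differ")
    potential = potential or PairPotential()
    Th, yh = h2o.temperature, h2o.shift
    Td, yd = d2o.temperature, d2o.shift
    y_all = np.concatenate([yh, yd])
    exps = (e1, e2)

    def _solve_linear(q: np.ndarray):
        """Basis at nonlinear parameters q and the projected (D1, D2)."""
        R, rho0, a7, Ts = q
        rho_h = rho0 - a7 * 1e-7 * (Th - Ts) ** 2
        rho_d = d2o_density.rho0 - d2o_density.a_s * (Td - d2o_density.t_max) ** 2
        if np.any(rho_h <= 0) or np.any(rho_d <= 0):
            return None
        area = 4.0 * np.pi * R * R
        grids = _radial_grids(potential, R, exps, n_r, n_u)
        B = np.vstack(
            [
                _basis_matrix(*grids, Th, rho_h * area),
                _basis_matrix(*grids, Td, rho_d * area),
            ]
        )
        if not np.all(np.isfinite(B)):
            return None
        D, *_ = np.linalg.lstsq(B, y_all, rcond=None)
        if D[0] <= 0:
            # Shallow-term coefficient must stay positive; pin it at the
            # boundary and refit the steep term alone.
            d2_only, *_ = np.linalg.lstsq(B[:, 1:], y_all, rcond=None)
            D = np.array([0.0, d2_only[0]])
        return B, D

    def residuals(q: np.ndarray) -> np.ndarray:
        out = _solve_linear(q)
        if out is None:
            return np.full(y_all.shape, 1e6)
        B, D = out
        return B @ D - y_all

    # Vertex of the H2O series seeds the density-peak temperature.
    try:
        ts_guess = fit_parabola(h2o).t_max - 40.0
    except FitError:
        ts_guess = 280.0
    rng = np.random.default_rng(seed)
    radii = (3.9, 4.1, 4.3, 3.7, 4.5, 3.5, 4.7, 4.9)
    lo = [3.0, 1e-4, -100.0, 150.0]
    hi = [6.0, 1.0, 100.0, 450.0]
    starts = []
    if initial is not None:
        dh = initial.density_h2o
        starts.append(np.array([initial.r, dh.rho0, dh.a_s * 1e7, dh.t_max]))
    for i in range(n_starts):
        starts.append(
            np.array(
                [
                    radii[i % len(radii)],
                    d2o_density.rho0 * (1.0 + 0.03 * rng.random()),
                    d2o_density.a_s * 1e7 * (1.0 + 0.2 * rng.random()),
                    ts_guess + 5.0 * rng.standard_normal(),
                ]
            )
        )
    best = None
    for q0 in starts:
        q0 = np.clip(q0, lo, hi)
        try:
            sol = least_squares(
                residuals,
                q0,
                bounds=(lo, hi),
                x_scale=[0.2, 0.01, 1.0, 10.0],
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no fit start converged")
    R, rho0, a7, Ts = best.x
    linear = _solve_linear(best.x)
    if linear is None:  # pragma: no cover - best.x was evaluable above
        raise FitError("best solution left the model's validity range")
    _, D = linear
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return FTEParameters(
        d1=float(D[0]),
        d2=float(D[1]),
        e1=e1,
        e2=e2,
        r=float(R),
        density_h2o=SurfaceDensityModel(float(rho0), float(a7) * 1e-7, float(Ts), "H2O"),
        density_d2o=d2o_density,
        rms=rms,
        converged=bool(best.success),
    )


def scan_exponents(
    h2o: ShiftSeries,
    d2o: ShiftSeries,
    e1_values,
    e2_values,
    d2o_density: SurfaceDensityModel = DENSITY_D2O,
    potential: PairPotential | None = None,
    *,
    seed: int = 0,
    n_starts: int = 3,
    **kwargs,
) -> list[tuple[int, int, FTEParameters]]:
    """Fit every admissible integer-exponent pair (E1 < E2), ranked by RMS.

    Evaluation order does not affect the ranking: each pair's fit is
    independent and ties break on (E1, E2).
    """
    pairs = sorted(
        {(int(a), int(b)) for a in e1_values for b in e2_values if a < b}
    )
    if not pairs:
        raise FitError("no admissible exponent pair in the scan ranges")
    results = []
    for a, b in pairs:
        try:
            fit = fit_fte(
                h2o, d2o, d2o_density, potential, a, b,
                seed=seed, n_starts=n_starts, **kwargs,
            )
        except FitError:
            continue
        results.append((a, b, fit))
    if not results:
        raise FitError("every exponent-pair fit failed")
    return sorted(results, key=lambda t: (t[2].rms, t[0], t[1]))


def curve_maximum(
    bundle: CavityModelBundle,
    t_lo: float,
    t_hi: float,
    step: float = 0.1,
    *,
    n_r: int = 256,
    n_u: int = 64,
) -> tuple[float, float]:
    """Locate the maximum of a constant-radius cavity-model curve.

    Returns ``(T_at_max, delta_max)`` on a uniform grid of the given
    step; the shell engine is built once since R is constant.
    """
    if bundle.geometry.a_r != 0.0:
        raise ValueError("curve_maximum assumes a temperature-independent R")
    T = np.arange(t_lo, t_hi + 0.5 * step, step)
    eng = _ShellEngine(
        bundle.shift_function, bundle.potential, bundle.geometry.r0, n_r, n_u
    )
    deltas = np.empty_like(T)
    for i, t in enumerate(T):
        _, Z, _ = bundle.structure_at(t)
        deltas[i] = eng.delta(t, Z)
    k = int(np.argmax(deltas))
    return float(T[k]), float(deltas[k])
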