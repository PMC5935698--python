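"""Semianalytical cavity-shell model of the Xe(aq) chemical shift.

The solvated xenon atom is pictured inside a thin spherical shell of
radius *R* carrying *Z* water molecules spread evenly over its surface
(surface density ``rho_S = Z / (4 pi R**2)``).  The xenon atom is not
pinned at the centre: its radial position ``r`` inside the shell is
Boltzmann-distributed according to the shell-averaged pair potential.
The observable shift is the Boltzmann radial average of the
shell-averaged pair shift,

    delta(T) = ∫ S(r) exp(-U(r)/kT) r^2 dr / ∫ exp(-U(r)/kT) r^2 dr,

with ``S(r) = Z * <delta_pair>_shell(r)`` and
``U(r) = Z * <V>_shell(r)``.  The model factorizes as
``delta(T) = rho_S(T) * K(T)``: a local-density factor ``rho_S``
(peaked near the solvent's density maximum) times a collision factor
``K`` that grows with temperature because hotter xenon penetrates
closer to the shell wall where the steep pair-shift function is large.
The competition between the two factors produces a shift maximum at a
higher temperature than the density maximum.

Temperature trends of the shell structure are quadratic vertex-form
polynomials: coordination number ``Z(T) = Z0 - a_Z (T - T_Z_max)^2``,
cavity radius ``R(T) = R0 + a_R (T - T_R_min)^2`` and surface density
``rho_S(T) = rho0 - a_S (T - T_S_max)^2`` (one density parameter set
per solvent isotope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from functools import lru_cache

from numpy.polynomial.legendre import leggauss as _leggauss
from scipy.integrate import quad

from .pairfunctions import (
    KB_KCAL_MOL_K,
    DomainError,
    PairPotential,
    PairShiftFunction,
)

__all__ = [
    "CoordinationModel",
    "CavityGeometry",
    "SurfaceDensityModel",
    "CavityShiftResult",
    "CavityModelBundle",
    "ModelValidityError",
    "eval_Z",
    "eval_R",
    "eval_surface_density",
    "surface_density_from_structure",
    "shell_average",
    "shell_average_power",
    "shell_average_shift",
    "boltzmann_shift",
    "temperature_sweep",
    "Z_TREND_MD",
    "R_TREND_MD",
    "DENSITY_D2O",
    "DENSITY_H2O",
    "R_FTE",
]


class ModelValidityError(ValueError):
    """A trend model was evaluated outside its physical validity range."""


@dataclass(frozen=True)
class CoordinationModel:
    """Quadratic trend of the first-shell coordination number.

    ``Z(T) = z0 - a_z * (T - t_max)**2`` — a downward parabola whose
    vertex sits below the liquid range, so Z decreases over it.
    """

    z0: float
    a_z: float  # K^-2
    t_max: float  # K


@dataclass(frozen=True)
class CavityGeometry:
    """Cavity radius versus temperature, ``R(T) = r0 + a_r (T - t_min)**2``.

    ``a_r = 0`` gives a temperature-independent radius (used by the
    experiment-calibrated model, where R is a single fit parameter).
    """

    r0: float  # Å
    a_r: float = 0.0  # Å / K^2
    t_min: float = 0.0  # K

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("cavity radius must be positive")
        if self.a_r < 0:
            raise ValueError("radius trend must open upward (a_r >= 0)")

    @classmethod
    def constant(cls, radius: float) -> "CavityGeometry":
        return cls(r0=radius, a_r=0.0, t_min=0.0)


@dataclass(frozen=True)
class SurfaceDensityModel:
    """Quadratic trend of the shell surface density, per solvent isotope.

    ``rho_S(T) = rho0 - a_s (T - t_max)**2`` in Å^-2; the vertex
    temperature tracks (but need not equal) the solvent's density
    maximum.
    """

    rho0: float  # Å^-2
    a_s: float  # Å^-2 K^-2
    t_max: float  # K
    isotope: str = "H2O"


# MD-derived trend parameters for Xe in (heavy) water, 278-368 K.
Z_TREND_MD = CoordinationModel(z0=21.989, a_z=0.000126697, t_max=260.56)
R_TREND_MD = CavityGeometry(r0=4.2675, a_r=3.57311e-6, t_min=292.34)

# Experiment-calibrated surface densities and the common cavity radius.
DENSITY_D2O = SurfaceDensityModel(
    rho0=0.0959701, a_s=6.99326e-7, t_max=266.975, isotope="D2O"
)
DENSITY_H2O = SurfaceDensityModel(
    rho0=0.0985138, a_s=8.29205e-7, t_max=270.387, isotope="H2O"
)
R_FTE = 4.1423  # Å


def eval_Z(m: CoordinationModel, T):
    """Coordination number at temperature(s) ``T`` (K)."""
    T = np.asarray(T, dtype=float)
    out = m.z0 - m.a_z * (T - m.t_max) ** 2
    return out if out.ndim else float(out)


def eval_R(g: CavityGeometry, T):
    """Cavity radius (Å) at temperature(s) ``T`` (K)."""
    T = np.asarray(T, dtype=float)
    out = g.r0 + g.a_r * (T - g.t_min) ** 2
    return out if out.ndim else float(out)


def eval_surface_density(s: SurfaceDensityModel, T):
    """Shell surface density (Å^-2) at temperature(s) ``T`` (K).

    Raises :class:`ModelValidityError` if the quadratic drops to or
    below zero — the model has left its physically meaningful range.
    """
    T = np.asarray(T, dtype=float)
    out = s.rho0 - s.a_s * (T - s.t_max) ** 2
    if np.any(out <= 0):
        raise ModelValidityError(
            f"surface density model {s.isotope} is non-positive at the "
            "requested temperature"
        )
    return out if out.ndim else float(out)


def surface_density_from_structure(Z: float, R: float) -> float:
    """Surface density implied by a shell of Z molecules at radius R."""
    if R <= 0:
        raise DomainError("shell radius must be positive")
    return Z / (4.0 * np.pi * R * R)


# ---------------------------------------------------------------------------
# Shell averaging


def shell_average_power(E: float, R: float, r):
    """Average of ``u**-E`` over a sphere of radius R seen from offset r.

    For a point at distance ``r`` from the centre of a uniform
    spherical surface of radius ``R``, distances ``u`` to surface
    points are distributed with density ``u / (2 R r)`` on
    ``[R - r, R + r]``, giving the closed form

        <u**-E> = [u^(2-E)]_{R-r}^{R+r} / (2 R r (2 - E))     (E != 2)
        <u**-2> = ln((R+r)/(R-r)) / (2 R r)

    Vectorized over ``r``; ``r = 0`` returns ``R**-E``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= R):
        raise DomainError("offset must satisfy 0 <= r < R")
    lo, hi = R - r, R + r
    if E == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, np.log(hi / lo) / (2.0 * R * r), R ** -2.0)
    else:
        p = 2.0 - E
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                r > 0,
                (hi ** p - lo ** p) / (2.0 * R * r * p),
                R ** -float(E),
            )
    return out if out.ndim else float(out)


def shell_average_shift(f: PairShiftFunction, R: float, r):
    """Closed-form shell average of an inverse-power shift function."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for coeff, exp in f.terms:
        out += coeff * shell_average_power(exp, R, r)
    return out if out.ndim else float(out)


def shell_average(
    f: Callable[[float], float],
    R: float,
    r: float,
    *,
    rtol: float = 1e-8,
) -> float:
    """Uniform average of ``f`` over a sphere of radius R from offset r.

    Closed forms exist for inverse-power integrands
    (:func:`shell_average_power`); this generic version uses adaptive
    quadrature of ``(1 / (2 R r)) * ∫_{R-r}^{R+r} f(u) u du``.
    """
    if not 0 <= r < R:
        raise DomainError("offset must satisfy 0 <= r < R")
    if r == 0:
        return float(f(R))
    val, _ = quad(lambda u: f(u) * u, R - r, R + r, epsrel=rtol, limit=200)
    return val / (2.0 * R * r)


# ---------------------------------------------------------------------------
# Boltzmann radial averaging


@dataclass(frozen=True)
class CavityShiftResult:
    """One temperature point of the cavity model.

    ``delta = rhoS * K_factor`` by construction; ``Z`` and ``R`` record
    the shell structure actually used at this temperature.
    """

    T: float  # K
    rhoS: float  # Å^-2
    K_factor: float  # ppm Å^2
    delta: float  # ppm
    Z: float
    R: float  # Å


@lru_cache(maxsize=32)
def leggauss(n: int):
    """Cached Gauss-Legendre nodes/weights (rebuilt engines reuse them)."""
    return _leggauss(n)


class _ShellEngine:
    """Precomputed Gauss-Legendre grids for one cavity radius.

    Shell averages of the shift use their closed form; the potential's
    shell average uses an inner Gauss rule.  Rebuilding the engine is
    cheap, so temperature-dependent radii simply rebuild per T.
    """

    def __init__(
        self,
        shiftf: PairShiftFunction,
        potf: PairPotential,
        R: float,
        n_r: int = 160,
        n_u: int = 64,
    ) -> None:
        self.R = R
        x, w = leggauss(n_r)
        self.r = 0.5 * R * (x + 1.0)  # nodes on (0, R)
        self.wr = 0.5 * R * w
        self.s1 = shell_average_shift(shiftf, R, self.r)  # per-molecule shift
        xu, wu = leggauss(n_u)
        lo = R - self.r
        hi = R + self.r
        mid = 0.5 * (hi + lo)[:, None]
        half = 0.5 * (hi - lo)[:, None]
        u = mid + half * xu[None, :]
        vu = potf(u) * u
        integral = (vu * wu[None, :]).sum(axis=1) * half[:, 0]
        self.u1 = integral / (2.0 * R * self.r)  # per-molecule potential

    def delta(self, T: float, Z: float) -> float:
        w = -(Z * self.u1) / (KB_KCAL_MOL_K * T)
        w = w - w.max()  # common factor cancels in the ratio
        e = np.exp(np.clip(w, -745.0, 0.0))
        r2 = self.r * self.r
        den = float(np.sum(self.wr * e * r2))
        num = float(np.sum(self.wr * self.s1 * e * r2))
        return Z * num / den


def _adaptive_delta(
    shiftf: PairShiftFunction,
    potf: PairPotential,
    R: float,
    Z: float,
    T: float,
    rtol: float = 1e-8,
) -> float:
    """Reference evaluation with nested adaptive quadrature."""
    beta = 1.0 / (KB_KCAL_MOL_K * T)

    def u1(r: float) -> float:
        return shell_average(potf, R, r, rtol=rtol) if r > 0 else potf(R)

    # Locate the maximum of the log-weight on a probe grid so the
    # exponentials stay in range; the constant cancels in the ratio.
    probe = np.linspace(0.0, R * (1 - 1e-6), 400)
    wmax = max(-beta * Z * u1(r) for r in probe)

    def weight(r: float) -> float:
        w = -beta * Z * u1(r) - wmax
        return 0.0 if w < -745.0 else np.exp(w)

    def num_f(r: float) -> float:
        e = weight(r)
        if e == 0.0:
            return 0.0
        return shell_average_shift(shiftf, R, r) * e * r * r

    den, den_err = quad(
        lambda r: weight(r) * r * r, 0.0, R, epsrel=rtol, limit=200
    )
    num, num_err = quad(num_f, 0.0, R, epsrel=rtol, limit=200)
    if den <= 0 or not np.isfinite(num / den):
        raise FloatingPointError(
            f"Boltzmann average did not converge at T={T} K "
            f"(num={num:g}±{num_err:g}, den={den:g}±{den_err:g})"
        )
    return Z * num / den


@dataclass(frozen=True)
class CavityModelBundle:
    """Everything one temperature evaluation of the cavity model needs.

    When both a coordination model and a surface-density model are
    supplied, the density model takes precedence: ``rho_S`` is read
    from it and ``Z = rho_S * 4 pi R^2`` is derived, because the
    experiment-calibrated model parameterizes the density directly.
    """

    shift_function: PairShiftFunction
    potential: PairPotential
    geometry: CavityGeometry
    coordination: CoordinationModel | None = None
    density: SurfaceDensityModel | None = None

    def __post_init__(self) -> None:
        if self.coordination is None and self.density is None:
            raise ValueError(
                "either a coordination model or a surface-density model "
                "is required"
            )

    @classmethod
    def fte(cls, isotope: str = "H2O") -> "CavityModelBundle":
        """The experiment-calibrated bundle for one solvent isotope."""
        density = DENSITY_H2O if isotope.upper() == "H2O" else DENSITY_D2O
        return cls(
            shift_function=PairShiftFunction.fte(),
            potential=PairPotential(),
            geometry=CavityGeometry.constant(R_FTE),
            density=density,
        )

    def structure_at(self, T: float) -> tuple[float, float, float]:
        """Resolve (R, Z, rho_S) at one temperature."""
        R = eval_R(self.geometry, T)
        if self.density is not None:
            rho = eval_surface_density(self.density, T)
            Z = rho * 4.0 * np.pi * R * R
        else:
            Z = eval_Z(self.coordination, T)
            rho = surface_density_from_structure(Z, R)
        return R, Z, rho


def boltzmann_shift(
    bundle: CavityModelBundle,
    T: float,
    *,
    method: str = "gauss",
    n_r: int = 256,
    n_u: int = 64,
    rtol: float = 1e-8,
) -> CavityShiftResult:
    """Cavity-model shift at one temperature.

    ``method="gauss"`` (default) uses fixed-order Gauss-Legendre grids,
    ``method="adaptive"`` nested adaptive quadrature at relative
    tolerance ``rtol`` — slower, kept as the cross-checking reference.
    """
    if T <= 0:
        raise DomainError("temperature must be positive")
    R, Z, rho = bundle.structure_at(T)
    if method == "gauss":
        eng = _ShellEngine(bundle.shift_function, bundle.potential, R, n_r, n_u)
        delta = eng.delta(T, Z)
    elif method == "adaptive":
        delta = _adaptive_delta(
            bundle.shift_function, bundle.potential, R, Z, T, rtol
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return CavityShiftResult(
        T=float(T), rhoS=rho, K_factor=delta / rho, delta=delta, Z=Z, R=R
    )


def temperature_sweep(
    bundle: CavityModelBundle,
    temperatures: Sequence[float],
    **kwargs,
) -> list[CavityShiftResult]:
    """Evaluate the cavity model on a temperature grid, order preserved."""
    temperatures = list(temperatures)
    if not temperatures:
        raise ValueError("temperature grid must be nonempty")
    results = []
    for T in temperatures:
        try:
            results.append(boltzmann_shift(bundle, T, **kwargs))
        except Exception as exc:
            raise RuntimeError(f"cavity model failed at T={T} K: {exc}") from exc
    return results
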