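"""Quadratic extremum fitting of shift-versus-temperature series.

The measured Xe(aq) shift curves are well described near their maximum
by a downward parabola

    delta(T) = delta_max - a_delta * (T - T_max)**2,

and (delta_max, T_max, a_delta) are the standard summary of a series.
Fitting is done in the polynomial basis (linear least squares, exact
on noiseless data) and converted to vertex form; standard errors come
from first-order propagation of the coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShiftSeries",
    "ParabolaFit",
    "ExtremumTypeError",
    "FitError",
    "fit_parabola",
    "predict",
    "sweep_difference",
    "EXPERIMENT_H2O",
    "EXPERIMENT_D2O",
]


class FitError(ValueError):
    """Singular or under-determined fit design."""


class ExtremumTypeError(FitError):
    """The series has no maximum-type extremum (wrong or zero curvature)."""


@dataclass(frozen=True)
class ShiftSeries:
    """Temperature-resolved chemical shifts, optionally with 1-sigma
    uncertainties and a heating/cooling sweep-direction tag per point."""

    temperature: np.ndarray  # K
    shift: np.ndarray  # ppm
    sigma: np.ndarray | None = None  # ppm
    label: str = ""
    direction: np.ndarray | None = None  # "up" / "down" per point

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float).ravel()
        d = np.asarray(self.shift, dtype=float).ravel()
        if T.shape != d.shape:
            raise ValueError("temperature and shift must have equal length")
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "shift", d)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float).ravel()
            if s.shape != T.shape:
                raise ValueError("sigma must match the series length")
            if np.any(s < 0):
                raise ValueError("sigma must be non-negative")
            object.__setattr__(self, "sigma", s)
        if self.direction is not None:
            object.__setattr__(
                self, "direction", np.asarray(self.direction).ravel()
            )

    def __len__(self) -> int:
        return len(self.temperature)


@dataclass(frozen=True)
class ParabolaFit:
    """Vertex-form description of a shift maximum.

    ``a_delta > 0`` by construction (the fit refuses minimum-type
    curvature); standard errors are zero for noiseless input.
    """

    delta_max: float  # ppm
    t_max: float  # K
    a_delta: float  # ppm / K^2
    se_delta_max: float = 0.0
    se_t_max: float = 0.0
    se_a_delta: float = 0.0
    rms: float = 0.0  # residual RMS, ppm
    label: str = ""


# Experimental parabola parameters of the Xe(aq) shift curves.
EXPERIMENT_H2O = ParabolaFit(
    delta_max=190.573, t_max=311.13, a_delta=1.4409e-3,
    se_delta_max=0.001, se_t_max=0.13, se_a_delta=0.013e-3, label="H2O",
)
EXPERIMENT_D2O = ParabolaFit(
    delta_max=186.707, t_max=315.33, a_delta=1.6029e-3,
    se_delta_max=0.014, se_t_max=0.14, se_a_delta=0.018e-3, label="D2O",
)


def fit_parabola(s: ShiftSeries) -> ParabolaFit:
    """Least-squares quadratic fit, reported in vertex form.

    Weighted by 1/sigma^2 when uncertainties are present (their
    covariance is then used directly); otherwise ordinary least
    squares with the residual variance estimated from the fit.
    """
    T, y = s.temperature, s.shift
    uniq = np.unique(T)
    if len(uniq) < 3:
        raise FitError("need at least 3 distinct temperatures")
    if len(uniq) != len(T):
        raise FitError("duplicate temperatures in fit input")
    if np.allclose(y, y[0]):
        raise FitError("all shifts equal; no trend to fit")

    mu, sd = T.mean(), T.std()
    t = (T - mu) / sd
    X = np.column_stack([np.ones_like(t), t, t * t])
    if s.sigma is not None and np.all(s.sigma > 0):
        w = 1.0 / s.sigma
        Xw, yw = X * w[:, None], y * w
        known_var = True
    else:
        Xw, yw = X, y
        known_var = False
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ coef
    rms = float(np.sqrt(np.mean(resid ** 2)))
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    if known_var:
        cov = XtX_inv
    else:
        dof = len(T) - 3
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = XtX_inv * s2

    c0, c1, c2 = coef
    if abs(c2) < 1e-12 * max(1.0, np.abs(y).max()):
        raise ExtremumTypeError("curvature indistinguishable from zero")
    if c2 > 0:
        raise ExtremumTypeError("series curves upward; no maximum")

    delta_max = c0 - c1 * c1 / (4.0 * c2)
    t_max = mu - sd * c1 / (2.0 * c2)
    a_delta = -c2 / sd ** 2
    # First-order propagation: gradients of the vertex parameters with
    # respect to (c0, c1, c2) in scaled coordinates.
    g_dm = np.array([1.0, -c1 / (2.0 * c2), c1 * c1 / (4.0 * c2 * c2)])
    g_tm = np.array([0.0, -sd / (2.0 * c2), sd * c1 / (2.0 * c2 * c2)])
    g_a = np.array([0.0, 0.0, -1.0 / sd ** 2])
    se = lambda g: float(np.sqrt(max(g @ cov @ g, 0.0)))
    return ParabolaFit(
        delta_max=float(delta_max),
        t_max=float(t_max),
        a_delta=float(a_delta),
        se_delta_max=se(g_dm),
        se_t_max=se(g_tm),
        se_a_delta=se(g_a),
        rms=rms,
        label=s.label,
    )


def predict(fit: ParabolaFit, temperatures) -> ShiftSeries:
    """Evaluate the fitted parabola on a temperature grid."""
    T = np.asarray(temperatures, dtype=float)
    d = fit.delta_max - fit.a_delta * (T - fit.t_max) ** 2
    return ShiftSeries(temperature=T, shift=d, label=fit.label)


def sweep_difference(s: ShiftSeries) -> float:
    """Mean shift difference between heating and cooling sweeps.

    A hysteresis diagnostic: near zero when the up- and down-sweep
    curves coincide.  Requires a per-point direction tag.
    """
    if s.direction is None:
        raise ValueError("series carries no sweep-direction labels")
    up = s.shift[s.direction == "up"]
    down = s.shift[s.direction == "down"]
    if up.size == 0 or down.size == 0:
        raise ValueError("need points in both sweep directions")
    return float(up.mean() - down.mean())
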