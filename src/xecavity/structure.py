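"""Solvation-shell structure analysis of explicit Xe + water configurations.

Given snapshots of one xenon atom surrounded by water molecules, this
module extracts the quantities the cavity model is parameterized from:
the Xe–O radial distribution function g(d), the first-minimum radius
r1 bounding the first solvation shell, per-frame coordination numbers
Z and cavity radii R, and quadratic temperature-trend fits of the
per-temperature shell statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cavity import CavityGeometry, CoordinationModel
from .pairfunctions import DomainError

__all__ = [
    "SolventConfiguration",
    "RDFResult",
    "ShellStatistics",
    "StructureError",
    "FitError",
    "xe_oxygen_distances",
    "compute_rdf",
    "find_first_minimum",
    "coordination_number",
    "cavity_radius",
    "shell_statistics",
    "fit_structural_trends",
]


class StructureError(ValueError):
    """The configuration lacks the structural feature being extracted."""


class FitError(ValueError):
    """A trend fit is degenerate or ill-posed."""


@dataclass(frozen=True)
class SolventConfiguration:
    """One Xe atom plus explicit water molecules.

    ``hydrogens`` has shape ``(n_water, 2, 3)`` and is carried for
    format fidelity; the shift and structure analyses here use Xe–O
    distances only.  ``box`` is a cubic box edge in Å (None for a
    non-periodic cluster); ``ref_density`` is the oxygen number
    density (Å^-3) to normalize cluster RDFs against.
    """

    xe: np.ndarray  # (3,)
    oxygens: np.ndarray  # (n, 3)
    hydrogens: np.ndarray  # (n, 2, 3)
    box: float | None = None
    temperature: float | None = None
    ref_density: float | None = None

    def __post_init__(self) -> None:
        xe = np.asarray(self.xe, dtype=float).reshape(3)
        ox = np.asarray(self.oxygens, dtype=float).reshape(-1, 3)
        hy = np.asarray(self.hydrogens, dtype=float).reshape(-1, 2, 3)
        if ox.shape[0] < 1:
            raise ValueError("configuration needs at least one water")
        if hy.shape[0] != ox.shape[0]:
            raise ValueError("one H pair required per oxygen")
        if not (np.isfinite(xe).all() and np.isfinite(ox).all() and np.isfinite(hy).all()):
            raise ValueError("coordinates must be finite")
        if self.box is not None and self.box <= 0:
            raise ValueError("box edge must be positive")
        object.__setattr__(self, "xe", xe)
        object.__setattr__(self, "oxygens", ox)
        object.__setattr__(self, "hydrogens", hy)

    @property
    def n_water(self) -> int:
        return self.oxygens.shape[0]


def xe_oxygen_distances(c: SolventConfiguration) -> np.ndarray:
    """Xe–O distances, minimum-image if the configuration is periodic."""
    d = c.oxygens - c.xe[None, :]
    if c.box is not None:
        d -= c.box * np.round(d / c.box)
    return np.linalg.norm(d, axis=1)


@dataclass(frozen=True)
class RDFResult:
    """Xe–O radial distribution function on a uniform grid."""

    bin_centers: np.ndarray  # Å
    g: np.ndarray
    bin_width: float  # Å
    r1: float | None = None  # first-minimum radius, Å

    def with_first_minimum(self) -> "RDFResult":
        return replace(self, r1=find_first_minimum(self))


def compute_rdf(
    configs: list[SolventConfiguration],
    bin_width: float = 0.05,
    max_radius: float | None = None,
) -> RDFResult:
    """Xe–O RDF averaged over frames at one temperature.

    Periodic frames are normalized by the ideal-gas shell count at the
    frame's own oxygen number density; non-periodic clusters use the
    declared ``ref_density``.  The default bin width of 0.05 Å resolves
    the first peak and minimum of the hydration shell.
    """
    if not configs:
        raise ValueError("need at least one configuration")
    temps = {c.temperature for c in configs}
    if len(temps) > 1:
        raise ValueError(f"mixed temperature labels in RDF input: {sorted(temps)}")
    if max_radius is None:
        if configs[0].box is not None:
            max_radius = configs[0].box / 2.0
        else:
            max_radius = float(
                max(xe_oxygen_distances(c).max() for c in configs)
            ) + 2.0 * bin_width
    n_bins = int(np.ceil(max_radius / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    expected = np.zeros(n_bins)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for c in configs:
        if c.box is not None:
            if max_radius > c.box / 2.0 + 1e-9:
                raise DomainError(
                    "max radius exceeds half the box edge under periodicity"
                )
            rho = c.n_water / c.box ** 3
        else:
            if c.ref_density is None:
                raise ValueError(
                    "cluster RDF requires a declared reference density"
                )
            rho = c.ref_density
        d = xe_oxygen_distances(c)
        counts += np.histogram(d, bins=edges)[0]
        expected += rho * shell_vol
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(bin_centers=centers, g=g, bin_width=bin_width)


def _smooth(g: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edges handled by shrinking the window."""
    half = window // 2
    out = np.empty_like(g)
    for i in range(len(g)):
        lo = max(0, i - half)
        hi = min(len(g), i + half + 1)
        out[i] = g[lo:hi].mean()
    return out


def find_first_minimum(r: RDFResult, smooth_window: int = 5) -> float:
    """First-minimum radius r1 of the RDF, bounding the first shell.

    The g curve is smoothed with a centered moving average (default
    5 bins) before locating the first peak exceeding 1 and the lowest
    bin between that peak and the subsequent rise (or the tail, if g
    never rises again, as for an isolated-shell cluster).
    """
    gs = _smooth(np.asarray(r.g, dtype=float), smooth_window)
    n = len(gs)
    above = np.nonzero(gs > 1.0)[0]
    if len(above) == 0:
        raise StructureError("no RDF peak above 1 found")
    i = int(above[0])
    while i + 1 < n and gs[i + 1] >= gs[i]:
        i += 1
    if i >= n - 1:
        raise StructureError("RDF still rising at the last bin; no minimum")
    peak = i
    # First local minimum after the peak; monotone/flat tails fall back
    # to the first occurrence of the post-peak global minimum.
    for j in range(peak + 1, n - 1):
        if gs[j] <= gs[j - 1] and gs[j] < gs[j + 1]:
            return float(r.bin_centers[j])
    j = peak + int(np.argmin(gs[peak:]))
    return float(r.bin_centers[j])


def coordination_number(c: SolventConfiguration, r1: float) -> int:
    """Number of oxygens within r1 of the xenon (minimum image)."""
    if r1 <= 0:
        raise DomainError("first-shell radius must be positive")
    return int(np.count_nonzero(xe_oxygen_distances(c) <= r1))


def cavity_radius(c: SolventConfiguration, r1: float) -> float:
    """Mean Xe–O distance over the first shell (oxygens within r1)."""
    d = xe_oxygen_distances(c)
    shell = d[d <= r1]
    if shell.size == 0:
        raise StructureError("no oxygen within the first-shell radius")
    return float(shell.mean())


@dataclass(frozen=True)
class ShellStatistics:
    """Per-temperature shell statistics averaged over frames."""

    temperature: float  # K
    z_mean: float
    z_sem: float
    r_mean: float  # Å
    r_sem: float  # Å
    n_frames: int


def shell_statistics(
    configs: list[SolventConfiguration], r1: float
) -> ShellStatistics:
    """Frame-averaged Z and R at one temperature."""
    if not configs:
        raise ValueError("need at least one configuration")
    temps = {c.temperature for c in configs}
    if len(temps) > 1:
        raise ValueError("mixed temperature labels")
    z = np.array([coordination_number(c, r1) for c in configs], dtype=float)
    r = np.array([cavity_radius(c, r1) for c in configs])
    n = len(configs)
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ShellStatistics(
        temperature=float(temps.pop()),
        z_mean=float(z.mean()),
        z_sem=sem(z),
        r_mean=float(r.mean()),
        r_sem=sem(r),
        n_frames=n,
    )


def _vertex_quadratic(T: np.ndarray, y: np.ndarray):
    """Least-squares quadratic in centered coordinates.

    Returns (c0, c1, c2) for ``y = c0 + c1 t + c2 t^2`` with
    ``t = T - mean(T)``, plus the centering offset.
    """
    mu = T.mean()
    t = T - mu
    X = np.column_stack([np.ones_like(t), t, t * t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef, mu


def fit_structural_trends(
    stats: list[ShellStatistics],
) -> tuple[CoordinationModel, CavityGeometry]:
    """Quadratic trend fits of Z(T) and R(T) from per-temperature stats.

    Z is fitted as a downward (maximum) parabola and R as an upward
    (minimum) parabola, both in vertex form.  Flat data yield a zero
    curvature with a NaN vertex temperature (unidentifiable).
    """
    T = np.array([s.temperature for s in stats], dtype=float)
    if len(np.unique(T)) < 3:
        raise FitError("need at least 3 distinct temperatures")
    if len(np.unique(T)) != len(T):
        raise FitError("repeated temperatures make the design degenerate")
    z = np.array([s.z_mean for s in stats])
    r = np.array([s.r_mean for s in stats])
    scale = T.std()

    (c0, c1, c2), mu = _vertex_quadratic(T, z)
    if abs(c2) * scale ** 2 < 1e-12 * max(1.0, abs(z).max()):
        zmodel = CoordinationModel(z0=float(z.mean()), a_z=0.0, t_max=np.nan)
    else:
        if c2 > 0:
            raise FitError("coordination trend curves upward; no maximum")
        tv = mu - c1 / (2.0 * c2)
        zmodel = CoordinationModel(
            z0=float(c0 - c1 * c1 / (4.0 * c2)), a_z=float(-c2), t_max=float(tv)
        )

    (b0, b1, b2), mu = _vertex_quadratic(T, r)
    if abs(b2) * scale ** 2 < 1e-12 * max(1.0, abs(r).max()):
        rmodel = CavityGeometry(r0=float(r.mean()), a_r=0.0, t_min=0.0)
    else:
        if b2 < 0:
            raise FitError("radius trend curves downward; no minimum")
        tv = mu - b1 / (2.0 * b2)
        rmodel = CavityGeometry(
            r0=float(b0 - b1 * b1 / (4.0 * b2)), a_r=float(b2), t_min=float(tv)
        )
    return zmodel, rmodel
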