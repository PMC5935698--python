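"""Synthetic inputs with the statistical structure the analysis assumes.

Real inputs to this pipeline are NMR temperature series and MD
solvation-shell snapshots, neither of which is publicly deposited.
This module generates stand-ins with the features the analysis relies
on: parabolic shift-vs-temperature series with Gaussian noise, and
first-solvation-shell geometries — Z water molecules scattered over a
sphere around the xenon with a Gaussian radial spread, oxygens kept
apart by a hard exclusion distance.  Multi-temperature "trajectories"
draw Z and the shell radius from the quadratic structural trend
models, emulating ensembles at ten temperatures spanning 278–368 K.

Everything is bit-reproducible under a fixed seed.  The shells are
deliberately idealized: no second shell, no hydrogen-bond network, no
dynamics — passing closure tests shows the analysis chain is
self-consistent, not that it reproduces real liquid water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cavity import CavityGeometry, CoordinationModel, eval_R, eval_Z
from .structure import SolventConfiguration
from .trends import ParabolaFit, ShiftSeries

__all__ = [
    "SyntheticSpec",
    "PackingError",
    "gen_experimental_series",
    "gen_configuration",
    "gen_trajectory",
]

# Gas-phase water monomer geometry; hydrogens are carried for format
# fidelity only (the shift function depends on the Xe-O distance).
OH_BOND = 0.9572  # Å
HOH_ANGLE_DEG = 104.52

#: Hard minimum O-O separation in generated shells (Å); prevents
#: unphysical overlap without attempting real liquid structure.
MIN_OO = 2.4

#: Radii are truncated below this Xe-O distance (Å); the repulsive
#: wall makes closer approaches vanishingly rare.
MIN_RADIUS = 2.5


class PackingError(RuntimeError):
    """The requested Z does not fit on the shell at the exclusion distance."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a multi-temperature toy trajectory.

    ``z_source`` / ``r_source`` may be constants or the quadratic trend
    models; defaults mirror an MD-style campaign: ten temperatures
    278–368 K in 10 K steps, shells of ~22 waters with a 0.25 Å radial
    spread.
    """

    seed: int = 0
    temperatures: tuple[float, ...] = tuple(np.arange(278.0, 369.0, 10.0))
    frames_per_temperature: int = 50
    radial_spread: float = 0.25  # Å
    z_source: float | CoordinationModel = 22.0
    r_source: float | CavityGeometry = 4.27  # Å
    box: float | None = None  # Å; None = non-periodic cluster
    noise_sigma: float = 0.05  # ppm, for generated shift series

    def __post_init__(self) -> None:
        if self.radial_spread < 0:
            raise ValueError("radial spread must be non-negative")
        if self.frames_per_temperature < 1:
            raise ValueError("need at least one frame per temperature")
        object.__setattr__(
            self, "temperatures", tuple(float(t) for t in self.temperatures)
        )


def gen_experimental_series(
    fit: ParabolaFit,
    temperatures,
    sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    label: str | None = None,
) -> ShiftSeries:
    """Parabolic shift series with optional Gaussian noise.

    ``delta(T) = delta_max - a_delta (T - T_max)^2 + N(0, sigma)``;
    the noise level is recorded in the series' per-point sigma.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    T = np.asarray(temperatures, dtype=float)
    d = fit.delta_max - fit.a_delta * (T - fit.t_max) ** 2
    if sigma > 0:
        d = d + rng.normal(0.0, sigma, size=T.shape)
    return ShiftSeries(
        temperature=T,
        shift=d,
        sigma=np.full(T.shape, sigma) if sigma > 0 else None,
        label=label if label is not None else fit.label,
    )


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _water_hydrogens(o: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two H positions at the monomer geometry in a random orientation."""
    half = np.deg2rad(HOH_ANGLE_DEG) / 2.0
    local = OH_BOND * np.array(
        [
            [np.sin(half), 0.0, np.cos(half)],
            [-np.sin(half), 0.0, np.cos(half)],
        ]
    )
    # Random rotation from a QR decomposition of a Gaussian matrix.
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return o[None, :] + local @ q.T


def gen_configuration(
    z: int,
    shell_center: float,
    spread: float,
    seed: int | np.random.Generator = 0,
    *,
    temperature: float | None = None,
    box: float | None = None,
    max_attempts: int = 20000,
) -> SolventConfiguration:
    """One xenon at the origin surrounded by a single solvation shell.

    Oxygen directions are uniform on the sphere, radii Gaussian about
    ``shell_center`` (truncated below 2.5 Å), subject to a 2.4 Å O-O
    exclusion enforced by rejection sampling.  Radii are drawn once per
    molecule and only the direction is re-drawn on rejection, keeping
    the radial marginal essentially the truncated Gaussian; only when a
    radius proves unplaceable (hundreds of failed directions) is that
    one radius re-drawn, a rare event with negligible bias.  Raises
    :class:`PackingError` when the attempt budget is exhausted —
    the requested Z does not fit on the shell.
    """
    if z < 1:
        raise ValueError("need at least one water")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if spread > 0:
        radii = np.empty(z)
        for i in range(z):
            r = rng.normal(shell_center, spread)
            while r <= MIN_RADIUS:
                r = rng.normal(shell_center, spread)
            radii[i] = r
    else:
        radii = np.full(z, float(shell_center))
        if shell_center <= MIN_RADIUS:
            raise ValueError("shell center must exceed the 2.5 Å floor")
    placed: list[np.ndarray] = []
    directions_per_radius = 400
    for i in range(z):
        attempts = 0
        placed_ok = False
        while not placed_ok:
            for _ in range(directions_per_radius):
                pos = radii[i] * _random_unit_vectors(rng, 1)[0]
                if all(np.linalg.norm(pos - p) >= MIN_OO for p in placed):
                    placed.append(pos)
                    placed_ok = True
                    break
            else:
                attempts += directions_per_radius
                if attempts >= max_attempts:
                    raise PackingError(
                        f"could not place oxygen {i + 1}/{z} on a "
                        f"{shell_center:.2f} Å shell with {MIN_OO} Å "
                        f"exclusion after {attempts} attempts"
                    )
                r = rng.normal(shell_center, spread) if spread > 0 else shell_center
                while r <= MIN_RADIUS:
                    r = rng.normal(shell_center, spread)
                radii[i] = r
    oxygens = np.array(placed)
    hydrogens = np.array([_water_hydrogens(o, rng) for o in oxygens])
    # Reference O density for cluster RDF normalization: shell count
    # over the sphere that encloses essentially all of the shell mass.
    r_ref = shell_center + 4.0 * max(spread, 1e-3)
    ref_density = z / (4.0 / 3.0 * np.pi * r_ref ** 3)
    return SolventConfiguration(
        xe=np.zeros(3),
        oxygens=oxygens,
        hydrogens=hydrogens,
        box=box,
        temperature=temperature,
        ref_density=ref_density,
    )


def _allocate_counts(
    value: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame integer water counts averaging to ``value``.

    Frames receive floor(value) or ceil(value) in the exact proportion
    of the fractional part (shuffled for frame-order variety), so the
    ensemble mean reproduces the trend value to within 1/(2 n_frames).
    Frame-to-frame occupation shot noise of a real simulation is
    deliberately not emulated; see the package documentation.
    """
    base = int(np.floor(value))
    n_high = int(round((value - base) * n_frames))
    counts = np.full(n_frames, base, dtype=int)
    counts[:n_high] += 1
    rng.shuffle(counts)
    return np.maximum(counts, 1)


def gen_trajectory(spec: SyntheticSpec) -> dict[float, list[SolventConfiguration]]:
    """Multi-temperature shell ensemble, grouped by temperature.

    Per temperature, frame water counts are allocated around Z(T) so the
    ensemble mean matches the trend model, and the shell center is R(T);
    both sources may be constants.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[float, list[SolventConfiguration]] = {}
    for T in spec.temperatures:
        z_target = (
            eval_Z(spec.z_source, T)
            if isinstance(spec.z_source, CoordinationModel)
            else float(spec.z_source)
        )
        center = (
            eval_R(spec.r_source, T)
            if isinstance(spec.r_source, CavityGeometry)
            else float(spec.r_source)
        )
        counts = _allocate_counts(z_target, spec.frames_per_temperature, rng)
        frames = []
        for k, z in enumerate(counts):
            try:
                frames.append(
                    gen_configuration(
                        z,
                        center,
                        spec.radial_spread,
                        rng,
                        temperature=T,
                        box=spec.box,
                    )
                )
            except PackingError as exc:
                raise PackingError(
                    f"frame {k} at T={T} K: {exc}"
                ) from exc
        out[T] = frames
    return out
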