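"""Binary Xe–water interaction functions.

The two ingredients of the cavity model are a binary chemical-shift
function — the shift a single water molecule at Xe–O distance *d*
induces on the xenon nucleus, expressed as a sum of inverse-power
terms ``delta_pair(d) = sum_n D_n / d**E_n`` — and a pair potential
used for Boltzmann weighting of the xenon position inside its
solvation cavity.  A constant relativistic/basis-set offset completes
the set: heavy-atom relativistic effects on the Xe shielding are well
approximated by a temperature-independent additive shift.

Units throughout: distances in Å, energies in kcal/mol, shifts in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

#: Boltzmann constant in kcal/(mol K), matching the kcal/mol energy scale.
KB_KCAL_MOL_K = 1.9872041e-3

# Empirical calibration of the two-term shift function for Xe in water
# (shared between the H2O and D2O solvent isotopes).
FTE_D1 = 1.85791e8    # ppm Å^12
FTE_D2 = -1.81437e10  # ppm Å^17
FTE_E1 = 12
FTE_E2 = 17

# Xe van der Waals parameters from the plain buffered 14-7 fit of the
# Xe–H2O dimer potential (well position Å, well depth kcal/mol).
VDW_R0 = 4.15
VDW_EPSILON = 2.362


class DomainError(ValueError):
    """An argument is outside the mathematical domain of the function."""


@dataclass(frozen=True)
class PairShiftFunction:
    """Binary chemical-shift function as a sum of inverse-power terms.

    Parameters
    ----------
    terms
        Sequence of ``(D_n, E_n)`` pairs; ``D_n`` in ppm·Å^E_n, ``E_n``
        a positive integer exponent.  Mixed-sign coefficient sets are
        allowed (the calibrated Xe–water set has ``D_2 < 0``); the value
        always decays to zero at large distance.
    """

    terms: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        terms = tuple((float(d), int(e)) for d, e in self.terms)
        for _, e in terms:
            if e < 1:
                raise ValueError(f"exponents must be positive integers, got {e}")
        object.__setattr__(self, "terms", terms)

    @classmethod
    def fte(cls) -> "PairShiftFunction":
        """The experiment-calibrated two-term Xe–water shift function."""
        return cls(((FTE_D1, FTE_E1), (FTE_D2, FTE_E2)))

    def __call__(self, d):
        return eval_pair_shift(self, d)


def eval_pair_shift(f: PairShiftFunction, d):
    """Evaluate ``sum_n D_n / d**E_n`` at Xe–O distance(s) ``d`` (Å).

    Accepts scalars or arrays; raises :class:`DomainError` for any
    non-positive distance.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DomainError("pair shift is defined for distances d > 0 only")
    out = np.zeros_like(d)
    for coeff, exp in f.terms:
        out += coeff * d ** (-exp)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PairPotential:
    """Isotropic Xe–water pair potential.

    Three forms are supported:

    ``"buffered-14-7"``
        The Halgren buffered 14-7 used by polarizable force fields:
        ``V(d) = eps * (1.07/(rho+0.07))**7 * (1.12/(rho**7+0.12) - 2)``
        with ``rho = d/R0``.  Minimum of ``-eps`` at ``d = R0``.
    ``"lennard-jones"``
        ``V(d) = eps * ((R0/d)**12 - 2 (R0/d)**6)``, same well convention.
    ``"tabulated"``
        Linear interpolation of a user-supplied ``(d, V)`` table; above
        the table the energy is clamped to 0, below it a
        :class:`DomainError` is raised (the table owner must cover the
        repulsive wall they care about).
    """

    form: str = "buffered-14-7"
    r0: float = VDW_R0
    epsilon: float = VDW_EPSILON
    table: tuple[tuple[float, float], ...] | None = None

    _FORMS = ("buffered-14-7", "lennard-jones", "tabulated")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.form == "tabulated":
            if not self.table:
                raise ValueError("tabulated form requires a (d, V) table")
            tab = tuple(sorted((float(d), float(v)) for d, v in self.table))
            object.__setattr__(self, "table", tab)
        elif self.r0 <= 0 or self.epsilon <= 0:
            raise ValueError("analytic forms require R0 > 0 and epsilon > 0")

    def __call__(self, d):
        return eval_pair_potential(self, d)


def eval_pair_potential(p: PairPotential, d):
    """Pair energy (kcal/mol) at distance(s) ``d`` (Å)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DomainError("pair potential is defined for distances d > 0 only")
    if p.form == "buffered-14-7":
        rho = d / p.r0
        out = p.epsilon * (1.07 / (rho + 0.07)) ** 7 * (1.12 / (rho ** 7 + 0.12) - 2.0)
    elif p.form == "lennard-jones":
        s6 = (p.r0 / d) ** 6
        out = p.epsilon * (s6 * s6 - 2.0 * s6)
    else:
        xs = np.array([x for x, _ in p.table])
        ys = np.array([y for _, y in p.table])
        if np.any(d < xs[0]):
            raise DomainError(
                f"distance below tabulated range (min {xs[0]:g} Å)"
            )
        out = np.interp(d, xs, ys, right=0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RelativisticOffset:
    """Constant additive correction to computed Xe shifts, in ppm.

    The default +44.7 ppm combines a scalar/spin–orbit relativistic
    contribution (30.3 ppm) with a basis-set improvement (14.4 ppm);
    both are temperature independent to good accuracy and are applied
    as a systematic offset.
    """

    offset: float = 44.7
    components: tuple[float, ...] = field(default=(30.3, 14.4))

    def __post_init__(self) -> None:
        if self.components and not np.isclose(
            sum(self.components), self.offset, atol=1e-9
        ):
            raise ValueError(
                "offset must equal the sum of its components when given"
            )


def apply_relativistic_offset(values, o: RelativisticOffset = RelativisticOffset()):
    """Add the constant offset to a shift value or array of shifts.

    Uncertainties attached elsewhere are unaffected — an additive
    constant shifts every draw identically.
    """
    arr = np.asarray(values, dtype=float) + o.offset
    return arr if arr.ndim else float(arr)
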