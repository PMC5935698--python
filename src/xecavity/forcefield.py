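"""Pairwise-additive chemical-shift evaluation over explicit configurations.

The "NMR force field" idea: once a binary shift function delta_pair(d)
is in hand, the shift of a solvated xenon in any snapshot is just the
sum of pair contributions from the surrounding waters — no electronic
structure calculation per frame.  Whether the coefficients encode a
strictly binary or an effective (many-body-absorbing) parameterization
is a property of the coefficient set, not of this code path.

Only Xe–O distances enter the pair function; hydrogen positions are
carried by the configurations but unused unless a coefficient set for
the H site is supplied as extra shift terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np

from .pairfunctions import DomainError, PairShiftFunction, eval_pair_shift
from .structure import SolventConfiguration, xe_oxygen_distances

__all__ = [
    "EnsembleShiftPoint",
    "config_shift",
    "ensemble_average",
    "DEFAULT_CUTOFF",
]

#: Default Xe–O cutoff (Å): approximately the first-shell radius;
#: contributions beyond it are small but not zero — an approximation.
DEFAULT_CUTOFF = 5.5


@dataclass(frozen=True)
class EnsembleShiftPoint:
    """Per-temperature ensemble average of the pairwise-additive shift."""

    temperature: float  # K
    mean_shift: float  # ppm
    sem: float  # ppm
    n_frames: int


def config_shift(
    c: SolventConfiguration,
    f: PairShiftFunction,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Pairwise-additive shift of one frame: sum of delta_pair(d_XeO)
    over waters with Xe–O distance within the cutoff (minimum image)."""
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    d = xe_oxygen_distances(c)
    d = d[d <= cutoff]
    if d.size == 0:
        return 0.0
    return float(np.sum(eval_pair_shift(f, d)))


def ensemble_average(
    configs: list[SolventConfiguration],
    f: PairShiftFunction,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[EnsembleShiftPoint]:
    """Group frames by temperature label and average the frame shifts.

    Returns one point per temperature, sorted by temperature, with the
    standard error of the mean over frames (0 for a single frame).
    """
    if not configs:
        raise ValueError("no configurations to average")
    for c in configs:
        if c.temperature is None:
            raise ValueError("every frame needs a temperature label")
    keyed = sorted(configs, key=lambda c: c.temperature)
    points = []
    for T, group in groupby(keyed, key=lambda c: c.temperature):
        shifts = np.array([config_shift(c, f, cutoff) for c in group])
        n = len(shifts)
        sem = float(shifts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        points.append(
            EnsembleShiftPoint(
                temperature=float(T),
                mean_shift=float(shifts.mean()),
                sem=sem,
                n_frames=n,
            )
        )
    return points
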