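"""File formats: delimited shift series, extended-XYZ shells, YAML configs.

Series are plain delimited tables (comma or tab, autodetected) with a
header naming columns ``T``, ``delta`` and optionally ``sigma``.
Configurations travel as extended XYZ: an atom-count line, a comment
line of ``key=value`` metadata (``temperature``, ``box``,
``ref_density``), then one line per atom — exactly one Xe per frame
and waters as contiguous O, H, H triples.  Both formats round-trip to
full precision.  Model parameters are flat YAML mappings.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cavity import (
    CavityGeometry,
    CavityModelBundle,
    CoordinationModel,
    SurfaceDensityModel,
)
from .pairfunctions import PairPotential, PairShiftFunction
from .structure import SolventConfiguration
from .trends import ShiftSeries

__all__ = [
    "ParseError",
    "read_series",
    "write_series",
    "read_xyz",
    "write_xyz",
    "load_config",
    "save_config",
    "bundle_from_config",
    "bundle_to_config",
    "write_sweep",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


# ---------------------------------------------------------------------------
# Shift series tables


def read_series(path, label: str = "") -> ShiftSeries:
    """Read a delimited (comma/tab) series with columns T, delta[, sigma]."""
    path = Path(path)
    # Sniff the delimiter from the first non-comment line; the C parser
    # is then used with round-trip float conversion for exact IO.
    sep = ","
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                if "\t" in line:
                    sep = "\t"
                break
    try:
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    cols = {c.strip(): c for c in df.columns}
    for req in ("T", "delta"):
        if req not in cols:
            raise ParseError(f"{path}: missing required column {req!r}")
    for name in ("T", "delta", "sigma"):
        if name in cols:
            col = pd.to_numeric(df[cols[name]], errors="coerce")
            bad = np.nonzero(col.isna().to_numpy())[0]
            if len(bad):
                raise ParseError(
                    f"{path}: non-numeric {name!r} at data line {bad[0] + 1}"
                )
            df[cols[name]] = col
    T = df[cols["T"]].to_numpy(dtype=float)
    dup = pd.Series(T).duplicated()
    if dup.any():
        line = int(np.nonzero(dup.to_numpy())[0][0]) + 1
        raise ParseError(f"{path}: duplicated temperature at data line {line}")
    sigma = df[cols["sigma"]].to_numpy(dtype=float) if "sigma" in cols else None
    direction = (
        df[cols["direction"]].to_numpy() if "direction" in cols else None
    )
    return ShiftSeries(
        temperature=T,
        shift=df[cols["delta"]].to_numpy(dtype=float),
        sigma=sigma,
        label=label or path.stem,
        direction=direction,
    )


def write_series(s: ShiftSeries, path, sep: str = ",") -> None:
    """Write a series at full precision; columns T, delta[, sigma]."""
    data = {"T": s.temperature, "delta": s.shift}
    if s.sigma is not None:
        data["sigma"] = s.sigma
    if s.direction is not None:
        data["direction"] = s.direction
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write("# T: K, delta: ppm, sigma: ppm\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Extended XYZ


def _format_frame(c: SolventConfiguration, out: _io.TextIOBase) -> None:
    n = 1 + 3 * c.n_water
    meta = []
    if c.temperature is not None:
        meta.append(f"temperature={c.temperature:.6g}")
    if c.box is not None:
        meta.append(f"box={c.box:.10g}")
    if c.ref_density is not None:
        meta.append(f"ref_density={c.ref_density:.10g}")
    out.write(f"{n}\n{' '.join(meta)}\n")
    fmt = "{:2s} {:.10f} {:.10f} {:.10f}\n".format
    out.write(fmt("Xe", *c.xe))
    for o, (h1, h2) in zip(c.oxygens, c.hydrogens):
        out.write(fmt("O", *o))
        out.write(fmt("H", *h1))
        out.write(fmt("H", *h2))


def write_xyz(configs, path) -> None:
    """Write frames as extended XYZ (Xe first, waters as O,H,H triples)."""
    configs = [configs] if isinstance(configs, SolventConfiguration) else configs
    with open(path, "w") as fh:
        for c in configs:
            _format_frame(c, fh)


def read_xyz(path) -> list[SolventConfiguration]:
    """Read an extended-XYZ trajectory of Xe + water frames."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[SolventConfiguration] = []
    i, frame_idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: frame {frame_idx}: bad atom-count line {i + 1}"
            )
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise ParseError(
                f"{path}: frame {frame_idx}: truncated (expected {n} atoms)"
            )
        meta = {}
        for token in lines[i + 1].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
        atoms = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: frame {frame_idx}: bad atom line {i + 3 + j}"
                )
            try:
                atoms.append((parts[0], [float(x) for x in parts[1:4]]))
            except ValueError:
                raise ParseError(
                    f"{path}: frame {frame_idx}: non-numeric coordinate "
                    f"at line {i + 3 + j}"
                )
        xe = [a for a in atoms if a[0] == "Xe"]
        if len(xe) != 1:
            raise ParseError(
                f"{path}: frame {frame_idx}: expected exactly one Xe, "
                f"found {len(xe)}"
            )
        rest = [a for a in atoms if a[0] != "Xe"]
        if len(rest) % 3 != 0:
            raise ParseError(
                f"{path}: frame {frame_idx}: waters must be O,H,H triples"
            )
        oxygens, hydrogens = [], []
        for k in range(0, len(rest), 3):
            trio = rest[k : k + 3]
            if [a[0] for a in trio] != ["O", "H", "H"]:
                raise ParseError(
                    f"{path}: frame {frame_idx}: broken O,H,H triple at "
                    f"water {k // 3}"
                )
            oxygens.append(trio[0][1])
            hydrogens.append([trio[1][1], trio[2][1]])
        frames.append(
            SolventConfiguration(
                xe=np.array(xe[0][1]),
                oxygens=np.array(oxygens),
                hydrogens=np.array(hydrogens),
                box=float(meta["box"]) if "box" in meta else None,
                temperature=(
                    float(meta["temperature"]) if "temperature" in meta else None
                ),
                ref_density=(
                    float(meta["ref_density"]) if "ref_density" in meta else None
                ),
            )
        )
        i += 2 + n
        frame_idx += 1
    return frames


# ---------------------------------------------------------------------------
# YAML model configs


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data


def save_config(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def bundle_from_config(data: dict) -> CavityModelBundle:
    """Build a cavity-model bundle from a flat config mapping.

    Expected sections: ``shift`` (terms: [[D, E], ...]), ``potential``
    (form, r0, epsilon | table), ``geometry`` (r0[, a_r, t_min] or
    radius), optional ``coordination`` (z0, a_z, t_max) and
    ``density`` (rho0, a_s, t_max, isotope).
    """
    shift = PairShiftFunction(tuple(map(tuple, data["shift"]["terms"])))
    pot = data.get("potential", {})
    potential = PairPotential(
        form=pot.get("form", "buffered-14-7"),
        r0=pot.get("r0", PairPotential().r0),
        epsilon=pot.get("epsilon", PairPotential().epsilon),
        table=tuple(map(tuple, pot["table"])) if "table" in pot else None,
    )
    geo = data["geometry"]
    if "radius" in geo:
        geometry = CavityGeometry.constant(geo["radius"])
    else:
        geometry = CavityGeometry(
            r0=geo["r0"], a_r=geo.get("a_r", 0.0), t_min=geo.get("t_min", 0.0)
        )
    coordination = None
    if "coordination" in data:
        c = data["coordination"]
        coordination = CoordinationModel(c["z0"], c["a_z"], c["t_max"])
    density = None
    if "density" in data:
        d = data["density"]
        density = SurfaceDensityModel(
            d["rho0"], d["a_s"], d["t_max"], d.get("isotope", "H2O")
        )
    return CavityModelBundle(
        shift_function=shift,
        potential=potential,
        geometry=geometry,
        coordination=coordination,
        density=density,
    )


def bundle_to_config(bundle: CavityModelBundle) -> dict:
    data: dict = {
        "shift": {"terms": [[d, e] for d, e in bundle.shift_function.terms]},
        "potential": {
            "form": bundle.potential.form,
            "r0": bundle.potential.r0,
            "epsilon": bundle.potential.epsilon,
        },
        "geometry": {
            "r0": bundle.geometry.r0,
            "a_r": bundle.geometry.a_r,
            "t_min": bundle.geometry.t_min,
        },
    }
    if bundle.potential.table is not None:
        data["potential"]["table"] = [list(t) for t in bundle.potential.table]
    if bundle.coordination is not None:
        c = bundle.coordination
        data["coordination"] = {"z0": c.z0, "a_z": c.a_z, "t_max": c.t_max}
    if bundle.density is not None:
        d = bundle.density
        data["density"] = {
            "rho0": d.rho0, "a_s": d.a_s, "t_max": d.t_max, "isotope": d.isotope
        }
    return data


def write_sweep(results, path, sep: str = ",") -> None:
    """Write a temperature sweep as a delimited (T, rhoS, K, delta) table."""
    df = pd.DataFrame(
        {
            "T": [r.T for r in results],
            "rhoS": [r.rhoS for r in results],
            "K": [r.K_factor for r in results],
            "delta": [r.delta for r in results],
        }
    )
    with open(path, "w") as fh:
        fh.write("# T: K, rhoS: A^-2, K: ppm A^2, delta: ppm\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g")
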