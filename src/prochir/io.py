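"""File formats: multi-frame XYZ, Hessians, CSV tables.

All exchange formats are plain text; column names are documented in
docs/FORMATS.md.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from prochir.chiroptics import TransitionRecord
from prochir.wigner import MolecularGeometry

__all__ = [
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_hessian_text",
    "read_molden_frequencies",
    "read_transitions_csv",
    "write_spectrum_csv",
    "read_g_curve_csv",
    "write_trajectory_csv",
    "write_ensemble",
    "ATOMIC_MASSES",
]

#: standard atomic weights (amu) for the elements this package meets
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "He": 4.0026, "Li": 6.94, "Be": 9.0122,
    "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Ne": 20.180, "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098,
    "Ca": 40.078, "Br": 79.904, "I": 126.90,
}


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries the offending line number."""


def read_xyz(path) -> list:
    """Read a (multi-frame) XYZ file into MolecularGeometry frames.

    Standard dialect: atom-count line, comment line, then one
    ``element x y z`` line per atom.  An empty file yields an empty list.
    """
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(f"line {i + 1}: expected an atom count")
        if i + 1 + nat >= n_lines + 1 and nat > 0:
            raise XYZParseError(
                f"line {i + 1}: frame declares {nat} atoms but file ends early"
            )
        symbols, coords = [], []
        for j in range(nat):
            ln = i + 2 + j
            if ln >= n_lines:
                raise XYZParseError(
                    f"line {i + 1}: frame declares {nat} atoms but file ends early"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {ln + 1}: expected 'element x y z'")
            el = parts[0].capitalize()
            if el not in ATOMIC_MASSES:
                raise XYZParseError(f"line {ln + 1}: unknown element {parts[0]!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(f"line {ln + 1}: non-numeric coordinate")
            symbols.append(el)
            coords.append(xyz)
        frames.append(
            MolecularGeometry(
                symbols=symbols,
                masses=np.array([ATOMIC_MASSES[s] for s in symbols]),
                coords=np.array(coords),
            )
        )
        i += 2 + nat
    return frames


def write_xyz(geometries, path, comments=None, precision: int = 8) -> None:
    """Write frames as multi-frame XYZ (lossless at the written precision)."""
    geometries = list(geometries)
    with open(path, "w") as fh:
        for k, g in enumerate(geometries):
            comment = comments[k] if comments else f"frame {k}"
            fh.write(f"{g.n_atoms}\n{comment}\n")
            for s, (x, y, z) in zip(g.symbols, g.coords):
                fh.write(
                    f"{s:2s} {x:> {precision + 8}.{precision}f}"
                    f" {y:> {precision + 8}.{precision}f}"
                    f" {z:> {precision + 8}.{precision}f}\n"
                )


def read_hessian_text(path) -> np.ndarray:
    """Plain-text square matrix of second derivatives (kcal/mol/A^2)."""
    H = np.loadtxt(path)
    H = np.atleast_2d(H)
    if H.shape[0] != H.shape[1]:
        raise ValueError(f"Hessian in {path} is not square: {H.shape}")
    return H


def read_molden_frequencies(path) -> dict:
    """Frequencies/normal-mode sections of a Molden file.

    Supports [FREQ], [FR-COORD] (Bohr) and [FR-NORM-COORD]; other sections
    are ignored.  Returns {'frequencies_cm': ..., 'coords_aa': ...,
    'symbols': ..., 'modes': (n_modes, n_atoms, 3)}.
    """
    bohr = 0.529177210903
    lines = Path(path).read_text().splitlines()
    freqs, symbols, coords, modes = [], [], [], []
    section = None
    current = None
    for raw in lines:
        s = raw.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith("["):
            if low.startswith("[freq"):
                section = "freq"
            elif low.startswith("[fr-coord"):
                section = "coord"
            elif low.startswith("[fr-norm-coord"):
                section = "modes"
            else:
                section = None
            continue
        if section == "freq":
            freqs.append(float(s.split()[0]))
        elif section == "coord":
            p = s.split()
            symbols.append(p[0].capitalize())
            coords.append([float(x) * bohr for x in p[1:4]])
        elif section == "modes":
            if low.startswith("vibration"):
                current = []
                modes.append(current)
            else:
                current.append([float(x) for x in s.split()[:3]])
    if not freqs:
        raise ValueError(f"no [FREQ] section found in {path}")
    return {
        "frequencies_cm": np.array(freqs),
        "symbols": symbols,
        "coords_aa": np.array(coords) if coords else None,
        "modes": np.array(modes) if modes else None,
    }


def read_transitions_csv(path) -> list:
    """CSV of vertical excitations.

    Columns: energy_eV, strength, rotatory_strength[, geometry_id].
    """
    df = pd.read_csv(path)
    need = {"energy_eV", "strength", "rotatory_strength"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TransitionRecord(
                energy_ev=float(row["energy_eV"]),
                dipole_strength=float(row["strength"]),
                rotatory_strength=float(row["rotatory_strength"]),
                geometry_id=(int(row["geometry_id"])
                             if "geometry_id" in df.columns
                             and not math.isnan(row.get("geometry_id", float("nan")))
                             else None),
            )
        )
    return out


def write_spectrum_csv(spec, g, path) -> None:
    """Spectrum as CSV: wavelength_nm, energy_eV, eps, deps, g."""
    pd.DataFrame(
        {
            "wavelength_nm": spec.wavelength_nm,
            "energy_eV": spec.energy_ev,
            "eps": spec.eps,
            "deps": spec.deps,
            "g": g,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_g_curve_csv(path) -> tuple:
    """g(lambda) curve CSV with columns wavelength_nm, g."""
    df = pd.read_csv(path)
    if not {"wavelength_nm", "g"} <= set(df.columns):
        raise ValueError(f"{path}: need columns wavelength_nm, g")
    return df["wavelength_nm"].to_numpy(float), df["g"].to_numpy(float)


def write_trajectory_csv(traj, path) -> None:
    """Trajectory time series as CSV (angles in degrees)."""
    pd.DataFrame(
        {
            "t_fs": traj.t,
            "tau_deg": np.degrees(traj.tau),
            "phi_deg": np.degrees(traj.phi),
            "state": traj.state,
            "pop_S0": traj.pop[:, 0],
            "pop_S1": traj.pop[:, 1],
            "e_total_kcal_mol": traj.e_total,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def write_ensemble(ensemble, xyz_path, momenta_csv_path, symbols=None) -> None:
    """Phase-space ensemble as multi-frame XYZ plus a momenta CSV.

    For reduced-coordinate (2D) ensembles only the CSV is written.
    """
    pos = ensemble.positions
    if symbols is not None and pos.shape[1] % 3 == 0:
        geoms = [
            MolecularGeometry(
                symbols=symbols,
                masses=np.array([ATOMIC_MASSES[s] for s in symbols]),
                coords=p.reshape(-1, 3),
            )
            for p in pos
        ]
        write_xyz(geoms, xyz_path)
    cols = {f"q{i}": pos[:, i] for i in range(pos.shape[1])}
    cols.update({f"p{i}": ensemble.momenta[:, i] for i in range(pos.shape[1])})
    pd.DataFrame(cols).to_csv(momenta_csv_path, index=False, float_format="%.12g")
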