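"""External representations: fchk wavefunctions, punch multipole files,
XYZ geometries and descriptor tables.

The formatted-checkpoint (.fchk) dialect is the text key/value-block
layout: scalar lines ``Name  I/R  value`` and array blocks
``Name  I/R  N= <count>`` followed by 6 integers or 5 reals per line.
Coordinates are stored in Bohr and converted to Angstrom on read.
Density blocks ("Total SCF Density", "Total MP2 Density",
"Total CC Density") hold the lower triangle row-wise and are expanded
to full symmetric matrices.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .multipole_math import BOHR_ANGSTROM, MultipoleSeries
from ._solid import component_labels, n_components

__all__ = [
    "Atom", "Geometry", "GaussianShell", "WavefunctionData",
    "read_fchk", "write_fchk", "read_punch", "write_punch",
    "read_xyz", "write_xyz", "write_descriptor_table",
    "element_symbol", "atomic_number",
]

_ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]


def element_symbol(z: int) -> str:
    return _ELEMENTS[z] if 0 < z < len(_ELEMENTS) else f"Z{z}"


def atomic_number(symbol: str) -> int:
    try:
        return _ELEMENTS.index(symbol.capitalize())
    except ValueError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class Atom:
    symbol: str
    charge: float          # nuclear charge, e
    position: np.ndarray   # Angstrom

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.charge <= 0:
            raise ValueError("nuclear charge must be positive")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite atomic position")


@dataclass
class Geometry:
    """Ordered atoms; positions in Angstrom internally."""

    atoms: list

    @classmethod
    def from_arrays(cls, symbols, positions_ang, charges=None) -> "Geometry":
        if charges is None:
            charges = [atomic_number(s) for s in symbols]
        return cls([Atom(s, z, p) for s, z, p in
                    zip(symbols, charges, np.asarray(positions_ang, float))])

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def symbols(self) -> list:
        return [a.symbol for a in self.atoms]

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def __len__(self):
        return len(self.atoms)

    def transformed(self, rotation: np.ndarray, shift: np.ndarray) -> "Geometry":
        """New geometry with positions rotation @ (r + shift)."""
        pos = (self.positions + shift) @ np.asarray(rotation).T
        return Geometry.from_arrays(self.symbols, pos, self.nuclear_charges)


@dataclass
class GaussianShell:
    center: int                      # atom index
    l: int
    primitives: list                 # [(exponent a.u., contraction coeff)]
    pure: bool = True                # spherical for d and higher

    def __post_init__(self):
        if self.l < 0:
            raise ValueError("angular momentum must be >= 0")
        if not self.primitives:
            raise ValueError("shell needs at least one primitive")
        if any(a <= 0 for a, _ in self.primitives):
            raise ValueError("primitive exponents must be strictly positive")


@dataclass
class WavefunctionData:
    """Geometry + Gaussian basis + one selected density matrix."""

    geometry: Geometry
    shells: list
    density: np.ndarray
    density_label: str = "SCF"
    n_electrons: int | None = None

    def __post_init__(self):
        from ._gauss import nao_shell
        self.density = np.asarray(self.density, dtype=float)
        nao = sum(nao_shell(s.l, s.pure) for s in self.shells)
        if self.density.shape != (nao, nao):
            raise ValueError(
                f"density matrix is {self.density.shape}, basis implies {nao} AOs")
        if not np.allclose(self.density, self.density.T, atol=1e-10):
            raise ValueError("density matrix not symmetric to 1e-10")

    @property
    def nao(self) -> int:
        return self.density.shape[0]

    def electron_count(self) -> float:
        """Tr(D S) from the analytic overlap."""
        from ._gauss import ShellBasis
        S = ShellBasis(self.geometry, self.shells).overlap()
        return float(np.einsum("ij,ij->", self.density, S))


# ----------------------------------------------------------------------
# fchk
# ----------------------------------------------------------------------

_DENSITY_KEYS = {
    "SCF": "Total SCF Density",
    "MP2": "Total MP2 Density",
    "CC": "Total CC Density",
}

_SHELL_TYPE_TO_L = {0: 0, 1: 1, -1: -1, 2: 2, -2: 2, 3: 3, -3: 3, 4: 4, -4: 4}


class FchkError(ValueError):
    pass


def _parse_fchk_blocks(path):
    """Yield (name, kind, value-or-array, byte_offset) for every block."""
    blocks = {}
    with open(path, "r") as fh:
        lines = fh.readlines()
    offsets = np.cumsum([0] + [len(l) for l in lines])
    i = 0
    while i < len(lines):
        line = lines[i]
        if len(line) < 44 or line[43] not in "IRC":
            i += 1
            continue
        name = line[:40].strip()
        kind = line[43]
        rest = line[44:].split()
        if rest and rest[0] == "N=":
            n = int(rest[1])
            vals = []
            j = i + 1
            while len(vals) < n and j < len(lines):
                vals.extend(lines[j].split())
                j += 1
            if len(vals) != n:
                raise FchkError(
                    f"block {name!r} declares {n} values but {len(vals)} found "
                    f"(byte offset {offsets[i]})")
            try:
                arr = (np.array(vals, dtype=int) if kind == "I"
                       else np.array([float(v.replace('D', 'E')) for v in vals]))
            except ValueError as exc:
                raise FchkError(
                    f"malformed value in block {name!r} near byte offset "
                    f"{offsets[i]}: {exc}") from None
            blocks[name] = arr
            i = j
        else:
            if kind == "I":
                blocks[name] = int(rest[0])
            elif kind == "R":
                blocks[name] = float(rest[0].replace('D', 'E'))
            else:
                blocks[name] = " ".join(rest)
            i += 1
    return blocks


def read_fchk(path, density_choice: str = "SCF") -> WavefunctionData:
    """Read a formatted-checkpoint document.

    density_choice: 'SCF' (default, mirroring the usual DMA convention),
    'MP2' or 'CC'.  Coordinates are converted Bohr -> Angstrom; the
    lower-triangle density block is expanded to a full symmetric matrix.
    """
    blocks = _parse_fchk_blocks(path)
    try:
        natoms = blocks["Number of atoms"]
        znums = blocks["Atomic numbers"]
        coords = blocks["Current cartesian coordinates"].reshape(natoms, 3)
        stypes = blocks["Shell types"]
        nprims = blocks["Number of primitives per shell"]
        atmap = blocks["Shell to atom map"]
        exps = blocks["Primitive exponents"]
        coefs = blocks["Contraction coefficients"]
    except KeyError as exc:
        raise FchkError(f"missing required fchk block {exc}") from None
    charges = blocks.get("Nuclear charges", np.asarray(znums, dtype=float))
    geometry = Geometry.from_arrays(
        [element_symbol(int(z)) for z in znums],
        coords * BOHR_ANGSTROM, charges)

    sp_coefs = blocks.get("P(S=P) Contraction coefficients")
    shells = []
    p0 = 0
    for st, np_, am in zip(stypes, nprims, atmap):
        st = int(st)
        if st not in _SHELL_TYPE_TO_L:
            raise FchkError(f"unsupported shell type {st} (|l| > 4)")
        prims = list(zip(exps[p0:p0 + np_], coefs[p0:p0 + np_]))
        if st == -1:  # SP shell: split into s and p sharing exponents
            shells.append(GaussianShell(am - 1, 0, prims, pure=False))
            pprims = list(zip(exps[p0:p0 + np_], sp_coefs[p0:p0 + np_]))
            shells.append(GaussianShell(am - 1, 1, pprims, pure=False))
        else:
            shells.append(GaussianShell(am - 1, abs(st), prims, pure=st < 0))
        p0 += np_

    key = _DENSITY_KEYS.get(density_choice.upper())
    if key is None:
        raise FchkError(f"unknown density choice {density_choice!r}")
    if key not in blocks:
        avail = [lab for lab, k in _DENSITY_KEYS.items() if k in blocks]
        raise FchkError(
            f"density block {key!r} not present; available densities: {avail}")
    tri = blocks[key]
    nao = int((np.sqrt(8 * tri.size + 1) - 1) / 2)
    if nao * (nao + 1) // 2 != tri.size:
        raise FchkError(f"density block {key!r} has non-triangular length {tri.size}")
    dm = np.zeros((nao, nao))
    iu = np.tril_indices(nao)
    dm[iu] = tri
    dm = dm + dm.T - np.diag(np.diag(dm))
    return WavefunctionData(
        geometry, shells, dm, density_choice.upper(),
        n_electrons=blocks.get("Number of electrons"))


def write_fchk(path, wavefunction: WavefunctionData, *, title="qdma fchk",
               densities: dict | None = None, charge=0, multiplicity=1):
    """Write a formatted-checkpoint document (synthetic or converted data).

    `densities` maps labels ('SCF', 'MP2', 'CC') to full symmetric AO
    matrices; defaults to the wavefunction's own density under its label.
    """
    wfn = wavefunction
    if densities is None:
        densities = {wfn.density_label: wfn.density}
    geo = wfn.geometry
    lines = [title[:72], "SP        RHF                                Gen"]

    def scalar(name, kind, value):
        if kind == "I":
            lines.append(f"{name:<40}   I {int(value):>16d}")
        else:
            lines.append(f"{name:<40}   R {value:>22.15E}")

    def array(name, kind, values):
        values = np.asarray(values).ravel()
        lines.append(f"{name:<40}   {kind}   N= {values.size:>11d}")
        if kind == "I":
            for i in range(0, values.size, 6):
                lines.append("".join(f"{int(v):>12d}" for v in values[i:i + 6]))
        else:
            for i in range(0, values.size, 5):
                lines.append("".join(f"{v:>16.8E}" for v in values[i:i + 5]))

    nelec = wfn.n_electrons
    if nelec is None:
        nelec = int(round(geo.nuclear_charges.sum())) - charge
    scalar("Number of atoms", "I", len(geo))
    scalar("Charge", "I", charge)
    scalar("Multiplicity", "I", multiplicity)
    scalar("Number of electrons", "I", nelec)
    array("Atomic numbers", "I", [atomic_number(s) for s in geo.symbols])
    array("Nuclear charges", "R", geo.nuclear_charges)
    array("Current cartesian coordinates", "R",
          geo.positions / BOHR_ANGSTROM)
    stypes, nprim, atmap, exps, coefs = [], [], [], [], []
    for sh in wfn.shells:
        st = sh.l if (sh.l < 2 or not sh.pure) else -sh.l
        stypes.append(st)
        nprim.append(len(sh.primitives))
        atmap.append(sh.center + 1)
        exps.extend(a for a, _ in sh.primitives)
        coefs.extend(c for _, c in sh.primitives)
    scalar("Number of contracted shells", "I", len(wfn.shells))
    scalar("Number of primitive shells", "I", sum(nprim))
    scalar("Highest angular momentum", "I", max(sh.l for sh in wfn.shells))
    scalar("Largest degree of contraction", "I", max(nprim))
    array("Shell types", "I", stypes)
    array("Number of primitives per shell", "I", nprim)
    array("Shell to atom map", "I", atmap)
    array("Primitive exponents", "R", exps)
    array("Contraction coefficients", "R", coefs)
    for label, dm in densities.items():
        dm = np.asarray(dm)
        array(_DENSITY_KEYS[label.upper()], "R", dm[np.tril_indices(dm.shape[0])])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# punch (site-multipole listing)
# ----------------------------------------------------------------------

def write_punch(sites, path, comments=()):
    """Write a punch file: per site a header ``label x y z rank N`` then one
    line of Q_lk components per rank (10 significant digits, fixed widths)."""
    lines = ["! qdma punch: site multipoles (positions in Angstrom, Q_lk in a.u.)"]
    lines += [f"! {c}" for c in comments]
    for s in sites:
        if not np.all(np.isfinite(s.q)):
            raise ValueError(f"non-finite component on site {s.label!r}")
        x, y, z = s.position
        lines.append(f"{s.label or 'X':<8s} {x:>14.8f} {y:>14.8f} {z:>14.8f}"
                     f"  rank {s.lmax}")
        for l in range(s.lmax + 1):
            lines.append("  " + "".join(f"{v:>18.9E}" for v in s.rank(l)))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_punch(path):
    """Read a punch file back into a list of MultipoleSeries."""
    sites = []
    with open(path) as fh:
        raw = [l.rstrip("\n") for l in fh]
    lines = [l for l in raw if l.strip() and not l.lstrip().startswith("!")]
    i = 0
    while i < len(lines):
        head = lines[i].split()
        if len(head) < 6 or head[4].lower() != "rank":
            raise ValueError(f"malformed punch site header: {lines[i]!r}")
        label = head[0]
        pos = [float(v) for v in head[1:4]]
        lmax = int(head[5])
        q = np.zeros(n_components(lmax))
        i += 1
        for l in range(lmax + 1):
            if i >= len(lines):
                raise ValueError(
                    f"site {label!r} declares rank {lmax} but components end at rank {l - 1}")
            vals = lines[i].split()
            if len(vals) != 2 * l + 1:
                raise ValueError(
                    f"site {label!r} rank {l}: expected {2 * l + 1} components, "
                    f"got {len(vals)}")
            try:
                q[l * l: l * l + 2 * l + 1] = [float(v) for v in vals]
            except ValueError:
                raise ValueError(
                    f"non-numeric component for site {label!r} at rank {l}") from None
            i += 1
        sites.append(MultipoleSeries(pos, lmax, q, label))
    return sites


# ----------------------------------------------------------------------
# XYZ
# ----------------------------------------------------------------------

def read_xyz(path) -> Geometry:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    syms, pos = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        syms.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
    return Geometry.from_arrays(syms, pos)


def write_xyz(geometry: Geometry, path, comment=""):
    lines = [str(len(geometry)), comment]
    for a in geometry.atoms:
        x, y, z = a.position
        lines.append(f"{a.symbol:<3s} {x:>15.8f} {y:>15.8f} {z:>15.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# descriptor tables
# ----------------------------------------------------------------------

def write_descriptor_table(results, path, format="CSV"):
    """One row per molecule/ring: six raw values, six normalized values,
    reference metadata and orientation diagnostics.

    `results` items must provide ``as_record() -> dict`` (DescriptorSet does).
    """
    fmt = format.upper()
    if fmt not in ("CSV", "JSON"):
        raise ValueError(f"unknown descriptor table format {format!r}")
    records = [r.as_record() for r in results]
    if fmt == "JSON":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)
            fh.write("\n")
        return
    import pandas as pd
    from .aromaticity import DESCRIPTOR_NAMES
    cols = (["label"] + list(DESCRIPTOR_NAMES)
            + [f"{n}_norm" for n in DESCRIPTOR_NAMES]
            + ["reference", "ring_rms_ang", "normal_x", "normal_y", "normal_z"])
    df = pd.DataFrame(records)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df = df[cols] if len(df) else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False)
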