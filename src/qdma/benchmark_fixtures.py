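"""Deterministic benchmark fixtures: benzene and its distortion families,
linear molecules, classical point-charge sets with closed-form multipoles,
a cached density provider, and the trend-report harness.

Distortion conventions (angles in degrees, parameter 0 returns the base
geometry unchanged):
  T1  bond-length alternation: ring bonds alternate 1.39 -/+ dR/2 (D3h,
      planar, centroid preserved; C-H along the CCC bisector).
  T2  in-plane C-H rock: each C-H vector rotated in-plane by alpha,
      alternating sense around the ring.
  T3  boat: the para pair C1/C4 (and their hydrogens) lifted to +z so the
      centroid->carbon direction makes angle alpha with the plane.
  T4  chair: carbons (and hydrogens) alternate +z/-z by the same rule.
  T5  out-of-plane C-H wag: C-H bonds tilted out of plane by alpha with
      carbons fixed, alternating up/down.
"""
from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from math import cos, radians, sin

import numpy as np

from .io_formats import Geometry, WavefunctionData, read_fchk, write_fchk
from .multipole_math import BOHR_ANGSTROM

__all__ = [
    "RCC_BENZENE", "RCH_BENZENE", "RCO_CO2",
    "DistortionSpec", "build_benzene", "bond_alternation", "distort",
    "build_linear",
    "build_co2", "classical_fixture", "density_provider", "trend_report",
]

RCC_BENZENE = 1.39    # Angstrom, the equalized aromatic C-C bond
RCH_BENZENE = 1.09    # Angstrom (standard value; trends, not absolutes, matter)
RCO_CO2 = 1.162       # Angstrom, experimental C=O in CO2

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

_T_RANGE = {  # physical parameter ranges per distortion test
    "T1": (0.0, 0.4),     # Angstrom; keeps both bond lengths positive
    "T2": (0.0, 60.0),    # degrees
    "T3": (0.0, 60.0),
    "T4": (0.0, 60.0),
    "T5": (0.0, 60.0),
}


@dataclass
class DistortionSpec:
    test_id: str          # T1..T5
    parameter: float      # dR (Angstrom) for T1, angle (degrees) otherwise

    def __post_init__(self):
        tid = self.test_id.upper()
        if tid not in _T_RANGE:
            raise ValueError(f"unknown distortion test {self.test_id!r}")
        self.test_id = tid
        lo, hi = _T_RANGE[tid]
        if not (lo <= self.parameter < hi):
            raise ValueError(
                f"{tid} parameter {self.parameter} outside [{lo}, {hi})")


def _hexagon(radius: float) -> list:
    """Regular-hexagon vertices from sign-symmetric literals, so that
    symmetry-equivalent bond vectors are bitwise identical."""
    r2 = radius / 2.0
    h = radius * np.sqrt(3.0) / 2.0
    return [(radius, 0.0, 0.0), (r2, h, 0.0), (-r2, h, 0.0),
            (-radius, 0.0, 0.0), (-r2, -h, 0.0), (r2, -h, 0.0)]


def build_benzene() -> Geometry:
    """D6h benzene in the xy plane: centroid at origin, C1 on +x,
    R(C-C) = 1.39 A, R(C-H) = 1.09 A; atoms ordered C1..C6, H1..H6."""
    pos = _hexagon(RCC_BENZENE) + _hexagon(RCC_BENZENE + RCH_BENZENE)
    return Geometry.from_arrays(["C"] * 6 + ["H"] * 6, pos)


def bond_alternation(geometry: Geometry, ring=range(6)) -> float:
    """dR: difference between the mean lengths of the two alternating
    ring-bond classes (even-index bonds vs odd-index bonds).

    Class sums use exact (fsum) accumulation, so the symmetric base
    builder reports exactly 0.0.
    """
    import math
    ring = list(ring)
    p = geometry.positions[ring]
    n = len(ring)
    bonds = [float(np.linalg.norm(p[(k + 1) % n] - p[k])) for k in range(n)]
    even = math.fsum(bonds[0::2]) / len(bonds[0::2])
    odd = math.fsum(bonds[1::2]) / len(bonds[1::2])
    return abs(odd - even)


def _alternating_hexagon(a: float, b: float) -> np.ndarray:
    """Vertices of the planar hexagon with alternating side lengths a, b and
    all internal angles 120 deg, centroid at origin, first vertex on +x."""
    pts = [np.zeros(2)]
    for k in range(5):
        L = a if k % 2 == 0 else b
        th = radians(60.0 * k + 90.0)
        pts.append(pts[-1] + L * np.array([cos(th), sin(th)]))
    pts = np.array(pts)
    pts -= pts.mean(axis=0)
    # rotate so vertex 0 lies on +x
    ang = np.arctan2(pts[0, 1], pts[0, 0])
    c, s = cos(-ang), sin(-ang)
    return pts @ np.array([[c, s], [-s, c]]).T


def distort(spec: DistortionSpec, base: Geometry | None = None) -> Geometry:
    """Apply one distortion-family geometry change to canonical benzene."""
    if base is None:
        base = build_benzene()
    if spec.parameter == 0.0:
        return Geometry.from_arrays(base.symbols, base.positions,
                                    base.nuclear_charges)
    pos = base.positions.copy()
    tid = spec.test_id

    if tid == "T1":
        ring2d = _alternating_hexagon(RCC_BENZENE - spec.parameter / 2.0,
                                      RCC_BENZENE + spec.parameter / 2.0)
        pos[:6, :2] = ring2d
        pos[:6, 2] = 0.0
        for k in range(6):
            e1 = pos[:6][(k - 1) % 6] - pos[k]
            e2 = pos[:6][(k + 1) % 6] - pos[k]
            bis = e1 / np.linalg.norm(e1) + e2 / np.linalg.norm(e2)
            h_dir = -bis / np.linalg.norm(bis)
            pos[6 + k] = pos[k] + RCH_BENZENE * h_dir
    elif tid == "T2":
        al = radians(spec.parameter)
        for k in range(6):
            sgn = 1.0 if k % 2 == 0 else -1.0
            c, s = cos(sgn * al), sin(sgn * al)
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            pos[6 + k] = pos[k] + R @ (pos[6 + k] - pos[k])
    elif tid in ("T3", "T4"):
        al = radians(spec.parameter)
        for k in range(6):
            if tid == "T3":
                lift = 1.0 if k in (0, 3) else 0.0
            else:
                lift = 1.0 if k % 2 == 0 else -1.0
            dz = lift * np.linalg.norm(pos[k][:2]) * np.tan(al)
            pos[k, 2] += dz
            pos[6 + k, 2] += dz
    elif tid == "T5":
        al = radians(spec.parameter)
        for k in range(6):
            sgn = 1.0 if k % 2 == 0 else -1.0
            ch = pos[6 + k] - pos[k]
            L = np.linalg.norm(ch)
            u = ch / L
            pos[6 + k] = pos[k] + L * (cos(al) * u
                                       + sin(al) * sgn * np.array([0, 0, 1.0]))
    return Geometry.from_arrays(base.symbols, pos, base.nuclear_charges)


def build_linear(symbols, bond_lengths) -> Geometry:
    """Linear molecule on the z-axis, center of mass at the origin."""
    if len(bond_lengths) != len(symbols) - 1:
        raise ValueError("need one bond length per adjacent pair")
    z = np.concatenate([[0.0], np.cumsum(bond_lengths)])
    m = np.array([_MASSES[s] for s in symbols])
    z -= (m @ z) / m.sum()
    pos = np.zeros((len(symbols), 3))
    pos[:, 2] = z
    return Geometry.from_arrays(symbols, pos)


def build_co2() -> Geometry:
    """O=C=O on the z-axis, R(C-O) = 1.162 A, center of mass at origin."""
    return build_linear(["O", "C", "O"], [RCO_CO2, RCO_CO2])


_CLASSICAL = {
    # axial quadrupole: +1 at (0,0,+-1 a0), -2 at origin -> Q20 = +2 e a0^2
    "axial-quadrupole": [(1.0, (0.0, 0.0, BOHR_ANGSTROM)),
                         (1.0, (0.0, 0.0, -BOHR_ANGSTROM)),
                         (-2.0, (0.0, 0.0, 0.0))],
    # square quadrupole in the xy plane: only Q22c survives at rank 2
    "square-quadrupole": [(1.0, (BOHR_ANGSTROM, 0.0, 0.0)),
                          (1.0, (-BOHR_ANGSTROM, 0.0, 0.0)),
                          (-1.0, (0.0, BOHR_ANGSTROM, 0.0)),
                          (-1.0, (0.0, -BOHR_ANGSTROM, 0.0))],
    "single-charge": [(1.0, (0.3, -0.2, 0.5))],
    "dipole-pair": [(1.0, (0.0, 0.0, 0.5 * BOHR_ANGSTROM)),
                    (-1.0, (0.0, 0.0, -0.5 * BOHR_ANGSTROM))],
}


def classical_fixture(name: str):
    """Point-charge sets [(charge e, position Angstrom)] with closed-form
    multipoles, used as engine oracles."""
    if name not in _CLASSICAL:
        raise ValueError(
            f"unknown classical fixture {name!r}; available: {sorted(_CLASSICAL)}")
    return [(q, np.array(p)) for q, p in _CLASSICAL[name]]


# ----------------------------------------------------------------------
# density provider
# ----------------------------------------------------------------------

_BUNDLED_DIR = os.path.join(os.path.dirname(__file__), "data", "fchk")


def _request_key(geometry: Geometry, basis: str, method: str) -> str:
    h = hashlib.sha1()
    h.update(basis.lower().encode())
    h.update(method.upper().encode())
    for a in geometry.atoms:
        h.update(a.symbol.encode())
        h.update(np.round(a.position, 6).tobytes())
    return h.hexdigest()[:10]


def density_provider(geometry: Geometry, basis: str, method: str = "SCF",
                     label: str = "mol", cache_dir: str | None = None,
                     allow_compute: bool = True) -> WavefunctionData:
    """Wavefunction for (geometry, basis, method), served from the fixture
    cache when present, otherwise computed with the bundled RHF/MP2
    backend and (when `cache_dir` is writable) cached to an fchk document
    so later runs are reproducible without the backend."""
    method = method.upper()
    if method == "HF":
        method = "SCF"
    key = _request_key(geometry, basis, method)
    fname = f"{label}_{method.lower()}_{key}.fchk"
    search = [d for d in (cache_dir, _BUNDLED_DIR) if d]
    for d in search:
        path = os.path.join(d, fname)
        if os.path.exists(path):
            return read_fchk(path, density_choice=method)
    if not allow_compute:
        raise FileNotFoundError(
            f"no cached density {fname!r} in {search} and computation disabled; "
            "generate the fixture with the scf backend or point cache_dir at it")
    from .scf import build_shells, run_rhf, wavefunction_from_scf
    shells = build_shells(geometry, basis)
    res = run_rhf(geometry, shells)
    wfn = wavefunction_from_scf(geometry, shells, res, method)
    if cache_dir:
        os.makedirs(cache_dir, exist_ok=True)
        write_fchk(os.path.join(cache_dir, fname), wfn,
                   title=f"{label} {method}/{basis} (qdma scf backend)")
    return wfn


# ----------------------------------------------------------------------
# trend report
# ----------------------------------------------------------------------

def trend_report(series, expected_direction: str = "decreasing",
                 minor_threshold: float = 1e-3) -> dict:
    """Classify each descriptor's normalized-value sequence along a
    distortion series.

    series: list of (parameter, DescriptorSet) with normalized values set.
    Returns {descriptor: 'concordant' | 'minor-deviation' | 'discordant'}:
    concordant when every consecutive step moves in the expected
    direction, minor-deviation when a single inversion smaller than
    `minor_threshold` occurs, discordant otherwise.
    """
    from .aromaticity import DESCRIPTOR_NAMES
    if len(series) < 2:
        raise ValueError("trend classification needs at least two points")
    sgn = -1.0 if expected_direction.startswith("dec") else 1.0
    series = sorted(series, key=lambda t: t[0])
    report = {}
    for name in DESCRIPTOR_NAMES:
        vals = np.array([ds.normalized[name] for _, ds in series])
        steps = sgn * np.diff(vals)
        bad = steps < 0
        if not bad.any():
            report[name] = "concordant"
        elif bad.sum() == 1 and abs(steps[bad][0]) < minor_threshold:
            report[name] = "minor-deviation"
        else:
            report[name] = "discordant"
    return report
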