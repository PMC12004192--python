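"""Multipole tensor algebra.

Real regular solid harmonics, the Cartesian <-> spherical quadrupole
bridge, the rotation-invariant |Q2| magnitude, origin translation of
multipole series, and direct analytic molecular moments (the partition-free
reference against which the distributed analysis is validated).

Conventions
-----------
* Real (never complex) spherical components, Racah-normalized solid
  harmonics: R_00 = 1, R_10 = z, R_20 = (3z^2 - r^2)/2.  A rank-l
  component is in e*a0^l; rank-2 components are directly the e*a0^2
  quadrupole numbers chemists quote.
* Site positions are stored in Angstrom; displacement vectors are
  converted to Bohr (a0 = 0.529177 A) before entering any moment.
* Moments describe the total *charge* density: nuclei count +Z,
  electrons -1 each, so the rank-0 total is (sum Z) - N_electrons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import acos, degrees, sqrt

import numpy as np

from . import _solid
from ._solid import component_labels, flat_labels, n_components, offset

__all__ = [
    "BOHR_ANGSTROM",
    "MAGIC_ANGLE_DEG",
    "MultipoleSeries",
    "CartesianQuadrupole",
    "real_regular_harmonics",
    "cartesian_to_spherical_quadrupole",
    "spherical_to_cartesian_quadrupole",
    "q2_magnitude",
    "translate_series",
    "sum_series_at",
    "direct_moments",
    "rotate_rank2",
]

#: Bohr radius in Angstrom; the single length-conversion constant.
BOHR_ANGSTROM = 0.529177

#: Angle (degrees) at which the (3 cos^2 theta - 1)/2 factor of the zz
#: quadrupole integrand changes sign: acos(1/sqrt(3)) = 54.7356...
MAGIC_ANGLE_DEG = degrees(acos(1.0 / sqrt(3.0)))


@dataclass
class MultipoleSeries:
    """Real spherical multipole components attached to a spatial site.

    Parameters
    ----------
    position : (3,) array, Angstrom.
    lmax : highest rank carried.
    q : flat component array of length (lmax+1)^2 in the order
        (0,0), (1,0), (1,1c), (1,1s), (2,0), (2,1c), (2,1s), (2,2c), (2,2s), ...
        Units e*a0^l per rank.
    label : free-form site label ('C1', 'origin', ...).
    """

    position: np.ndarray
    lmax: int
    q: np.ndarray = None
    label: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.q is None:
            self.q = np.zeros(n_components(self.lmax))
        else:
            self.q = np.asarray(self.q, dtype=float).copy()
        if self.q.shape != (n_components(self.lmax),):
            raise ValueError(
                f"rank {self.lmax} requires {n_components(self.lmax)} components "
                f"(2l+1 per rank), got {self.q.shape[0]}"
            )
        if not np.all(np.isfinite(self.q)):
            raise ValueError("non-finite multipole component")

    def component(self, l: int, k: str) -> float:
        """Q_lk, e.g. component(2, '0') is Q20."""
        if l > self.lmax:
            raise ValueError(f"series carries ranks <= {self.lmax}, asked for l={l}")
        labels = component_labels(l)
        if k not in labels:
            raise KeyError(f"no component '{k}' at rank {l}")
        return float(self.q[offset(l) + labels.index(k)])

    def rank(self, l: int) -> np.ndarray:
        """The 2l+1 components of rank l (view order 0,1c,1s,...)."""
        if l > self.lmax:
            raise ValueError(f"series carries ranks <= {self.lmax}")
        return self.q[offset(l): offset(l) + 2 * l + 1]

    def with_lmax(self, lmax: int) -> "MultipoleSeries":
        """Copy, zero-padded or truncated to `lmax`."""
        q = np.zeros(n_components(lmax))
        n = min(q.size, self.q.size)
        q[:n] = self.q[:n]
        return MultipoleSeries(self.position, lmax, q, self.label)

    def copy(self) -> "MultipoleSeries":
        return MultipoleSeries(self.position, self.lmax, self.q, self.label)

    def items(self):
        for (l, k), v in zip(flat_labels(self.lmax), self.q):
            yield l, k, float(v)


@dataclass
class CartesianQuadrupole:
    """Traceless quadrupole tensor Theta_ab in e*a0^2."""

    xx: float
    yy: float
    zz: float
    xy: float = 0.0
    xz: float = 0.0
    yz: float = 0.0

    TRACE_TOL = 1e-10

    def __post_init__(self):
        tr = abs(self.xx + self.yy + self.zz)
        scale = max(1.0, float(np.abs(self.matrix()).max()))
        if tr > self.TRACE_TOL * scale:
            raise ValueError(f"quadrupole tensor not traceless: trace={tr:g}")

    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.xx, self.xy, self.xz],
                [self.xy, self.yy, self.yz],
                [self.xz, self.yz, self.zz],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "CartesianQuadrupole":
        m = np.asarray(m, dtype=float)
        return cls(m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2])


def real_regular_harmonics(r, lmax: int) -> dict:
    """Table {(l, k): R_lk(r)} of real regular solid harmonics at point r.

    `r` is a plain coordinate vector (no unit conversion is applied:
    feed Bohr to obtain atomic-unit moments).  R_00 = 1, R_10 = z,
    R_20 = (3z^2 - r^2)/2; homogeneous of degree l.
    """
    if lmax < 0:
        raise ValueError("lmax must be >= 0")
    vals = _solid.eval_real(np.asarray(r, dtype=float), lmax)
    return {lk: float(v) for lk, v in zip(flat_labels(lmax), vals)}


# rank-2 order: [Q20, Q21c, Q21s, Q22c, Q22s]
_SQ3 = sqrt(3.0)


def cartesian_to_spherical_quadrupole(theta: CartesianQuadrupole) -> np.ndarray:
    """Spherical rank-2 components [Q20, Q21c, Q21s, Q22c, Q22s] of Theta.

    Q20 = Theta_zz, Q21c = (2/sqrt3) Theta_xz, Q21s = (2/sqrt3) Theta_yz,
    Q22c = (1/sqrt3)(Theta_xx - Theta_yy), Q22s = (2/sqrt3) Theta_xy.
    """
    return np.array(
        [
            theta.zz,
            2.0 / _SQ3 * theta.xz,
            2.0 / _SQ3 * theta.yz,
            (theta.xx - theta.yy) / _SQ3,
            2.0 / _SQ3 * theta.xy,
        ]
    )


def spherical_to_cartesian_quadrupole(q2: np.ndarray) -> CartesianQuadrupole:
    """Inverse of :func:`cartesian_to_spherical_quadrupole`."""
    q2 = np.asarray(q2, dtype=float).reshape(5)
    q20, q21c, q21s, q22c, q22s = q2
    zz = q20
    xx = -0.5 * q20 + _SQ3 / 2.0 * q22c
    yy = -0.5 * q20 - _SQ3 / 2.0 * q22c
    return CartesianQuadrupole(
        xx=xx, yy=yy, zz=zz,
        xy=_SQ3 / 2.0 * q22s, xz=_SQ3 / 2.0 * q21c, yz=_SQ3 / 2.0 * q21s,
    )


def q2_magnitude(series) -> float:
    """|Q2| = Euclidean norm of the five rank-2 components (e*a0^2).

    Accepts a MultipoleSeries (rank >= 2 required) or a 5-vector.
    """
    if isinstance(series, MultipoleSeries):
        if series.lmax < 2:
            raise ValueError("|Q2| requires a series of rank >= 2")
        comp = series.rank(2)
    else:
        comp = np.asarray(series, dtype=float).reshape(5)
    return float(np.linalg.norm(comp))


def translate_series(series: MultipoleSeries, new_origin) -> MultipoleSeries:
    """Refer a multipole series to a new origin (Angstrom coordinates).

    Exact for terminating series: the result carries the same charge
    distribution's moments about `new_origin` for every rank <= lmax.
    """
    new_origin = np.asarray(new_origin, dtype=float).reshape(3)
    disp_bohr = (series.position - new_origin) / BOHR_ANGSTROM
    q = _solid.translation_apply(series.q, series.lmax, disp_bohr)
    return MultipoleSeries(new_origin, series.lmax, q, series.label)


def sum_series_at(origin, sites) -> MultipoleSeries:
    """Translate every site series to `origin` and sum componentwise.

    Series of unequal rank are zero-padded to the largest rank present.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no series to sum")
    lmax = max(s.lmax for s in sites)
    origin = np.asarray(origin, dtype=float).reshape(3)
    total = MultipoleSeries(origin, lmax, label="total")
    for s in sites:
        total.q += translate_series(s.with_lmax(lmax), origin).q
    return total


def direct_moments(wavefunction, origin, lmax: int) -> MultipoleSeries:
    """Molecular multipoles about `origin` by direct analytic integration.

    Evaluates the one-electron moment integrals of the real solid
    harmonics over the density matrix and adds the nuclear point
    contributions -- no partitioning.  Serves as the ground truth the
    distributed analysis must reproduce when its sites are recombined.
    """
    from ._gauss import ShellBasis  # deferred: keeps this module light

    origin = np.asarray(origin, dtype=float).reshape(3)
    basis = ShellBasis(wavefunction.geometry, wavefunction.shells)
    mom = basis.moment_matrices(origin, lmax)  # (ncomp, nao, nao)
    dm = np.asarray(wavefunction.density)
    q = -np.einsum("cij,ij->c", mom, dm)  # electrons carry charge -1
    # nuclear point charges
    for atom in wavefunction.geometry.atoms:
        d = (np.asarray(atom.position) - origin) / BOHR_ANGSTROM
        q += atom.charge * _solid.eval_real(d, lmax)
    return MultipoleSeries(origin, lmax, q, label="molecule")


def rotate_rank2(q2: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Rank-2 components after rigid rotation `rot` of the density.

    Routed through the Cartesian tensor: Theta' = R Theta R^T.
    """
    theta = spherical_to_cartesian_quadrupole(q2)
    rot = np.asarray(rot, dtype=float)
    m = rot @ theta.matrix() @ rot.T
    return cartesian_to_spherical_quadrupole(CartesianQuadrupole.from_matrix(m))
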