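"""Atom-centered molecular quadrature grid with Becke fuzzy-cell weights.

Used by the numerical allocation path for diffuse primitive pairs: the
diffuse part of the density is integrated point-by-point, each point's
charge being assigned to its (radius-scaled) nearest expansion site.

Radial: Gauss-Legendre on x in (-1,1) mapped through r = rm (1+x)/(1-x)
(rm is a per-element scale).  Angular: Gauss-Legendre in cos(theta) times
a uniform phi grid, exact for band-limited spherical integrands.
"""
from __future__ import annotations

import numpy as np

from .multipole_math import BOHR_ANGSTROM

# Becke radial scale per element (Bohr); hydrogen tighter than heavy atoms.
_RM_DEFAULT = 1.4
_RM = {"H": 0.8, "He": 0.8, "Li": 2.0, "Be": 1.8, "B": 1.6, "C": 1.4,
       "N": 1.3, "O": 1.2, "F": 1.1, "Ne": 1.0}


def _becke_step(mu: np.ndarray, k: int = 3) -> np.ndarray:
    f = np.array(mu, dtype=float, copy=True)
    for _ in range(k):
        f *= 1.5 - 0.5 * f * f
    f *= -0.5
    f += 0.5
    return f


def atom_grid(center_bohr, rm, nrad, ntheta, nphi):
    x, wx = np.polynomial.legendre.leggauss(nrad)
    r = rm * (1.0 + x) / (1.0 - x)
    wr = wx * 2.0 * rm / (1.0 - x) ** 2 * r ** 2
    ct, wt = np.polynomial.legendre.leggauss(ntheta)
    st = np.sqrt(1.0 - ct ** 2)
    phi = 2.0 * np.pi * np.arange(nphi) / nphi
    wphi = 2.0 * np.pi / nphi
    # build product grid
    R, CT, PHI = np.meshgrid(r, ct, phi, indexing="ij")
    ST = np.sqrt(1.0 - CT ** 2)
    pts = np.stack([R * ST * np.cos(PHI), R * ST * np.sin(PHI), R * CT],
                   axis=-1).reshape(-1, 3)
    w = (wr[:, None, None] * wt[None, :, None]
         * np.full(nphi, wphi)[None, None, :]).ravel()
    return pts + np.asarray(center_bohr), w


def molecular_grid(geometry, nrad=50, ntheta=18, nphi=36):
    """Becke-weighted union of atom grids; positions/weights in Bohr/a.u."""
    centers = geometry.positions / BOHR_ANGSTROM
    rms = np.array([_RM.get(s, _RM_DEFAULT) for s in geometry.symbols])
    all_pts, all_w, owners = [], [], []
    for i, (c, rm) in enumerate(zip(centers, rms)):
        pts, w = atom_grid(c, rm, nrad, ntheta, nphi)
        all_pts.append(pts)
        all_w.append(w)
        owners.append(np.full(len(w), i))
    pts = np.concatenate(all_pts)
    w = np.concatenate(all_w)
    owners = np.concatenate(owners)
    natom = len(centers)
    if natom > 1:
        # Becke cell functions
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        Rij = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        P = np.ones((len(pts), natom))
        for i in range(natom):
            for j in range(i + 1, natom):
                mu = (d[:, i] - d[:, j]) / Rij[i, j]
                s = _becke_step(mu)
                P[:, i] *= s
                P[:, j] *= 1.0 - s
        norm = P.sum(axis=1)
        w = w * P[np.arange(len(pts)), owners] / norm
    return pts, w
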