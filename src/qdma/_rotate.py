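"""Rigid transforms of wavefunctions: rotate the AO basis with the geometry.

A density matrix is tied to the molecular frame; re-orienting a geometry
requires conjugating the density with the per-shell rotation of the AO
components (monomial rotation for Cartesian shells, the induced real
Wigner rotation for pure shells).
"""
from __future__ import annotations

import numpy as np

from ._gauss import CART_ORDER, ncart, _pure_transform
from .io_formats import Geometry, WavefunctionData


def _monomial_rotation(l: int, rot: np.ndarray) -> np.ndarray:
    """W[i, j]: expansion of mono_i(R^T v) in mono_j(v) for degree-l monomials."""
    if l == 0:
        return np.eye(1)
    # linear forms (R^T v)_d = sum_e rot[e, d] v_e
    lin = [{(1 if e == 0 else 0, 1 if e == 1 else 0, 1 if e == 2 else 0):
            rot[e, d] for e in range(3)} for d in range(3)]
    monos = CART_ORDER[l]
    W = np.zeros((len(monos), len(monos)))
    for i, (a, b, c) in enumerate(monos):
        poly = {(0, 0, 0): 1.0}
        for d, power in enumerate((a, b, c)):
            for _ in range(power):
                new = {}
                for key, coef in poly.items():
                    for lkey, lcoef in lin[d].items():
                        nk = tuple(k + m for k, m in zip(key, lkey))
                        new[nk] = new.get(nk, 0.0) + coef * lcoef
                poly = new
        for key, coef in poly.items():
            W[i, monos.index(key)] = coef
    return W


def shell_rotation(l: int, pure: bool, rot: np.ndarray) -> np.ndarray:
    """AO-component rotation matrix U for one shell under rotation `rot`."""
    W = _monomial_rotation(l, rot)
    if not pure or l < 2:
        return W
    T = _pure_transform(l)
    return T @ W @ np.linalg.pinv(T)


def rotate_wavefunction(wfn: WavefunctionData, rotation: np.ndarray,
                        shift: np.ndarray) -> WavefunctionData:
    """Wavefunction on the rigidly transformed geometry r' = R (r + shift).

    The density matrix is conjugated so the transformed density satisfies
    rho'(R (r + shift)) = rho(r).
    """
    rot = np.asarray(rotation, dtype=float)
    geo = wfn.geometry.transformed(rot, shift)
    blocks = [shell_rotation(sh.l, sh.pure and sh.l >= 2, rot)
              for sh in wfn.shells]
    n = wfn.nao
    U = np.zeros((n, n))
    at = 0
    for B in blocks:
        k = B.shape[0]
        U[at: at + k, at: at + k] = B
        at += k
    dm = U.T @ wfn.density @ U
    dm = 0.5 * (dm + dm.T)
    return WavefunctionData(geo, list(wfn.shells), dm, wfn.density_label,
                            n_electrons=wfn.n_electrons)
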