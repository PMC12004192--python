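"""Minimal closed-shell RHF and unrelaxed MP2 densities.

A compact reference backend used to generate the bundled density
fixtures: conventional in-core ERIs, DIIS-accelerated SCF, and the
response-free (unrelaxed) MP2 one-particle density.  Closed shells only.
"""
from __future__ import annotations

import numpy as np

from .._gauss import ShellBasis
from ..io_formats import WavefunctionData
from ..multipole_math import BOHR_ANGSTROM
from .integrals import eri_tensor, nuclear_attraction, overlap_kinetic


class SCFResult:
    def __init__(self, **kw):
        self.__dict__.update(kw)


def run_rhf(geometry, shells, charge: int = 0, max_iter: int = 80,
            conv: float = 1e-9, verbose: bool = False) -> SCFResult:
    """Restricted Hartree-Fock; returns orbitals, density and energies."""
    basis = ShellBasis(geometry, shells)
    Z = geometry.nuclear_charges
    centers = geometry.positions / BOHR_ANGSTROM
    nelec = int(round(Z.sum())) - charge
    if nelec % 2:
        raise ValueError("closed-shell backend: even electron count required")
    nocc = nelec // 2

    S, T = overlap_kinetic(basis)
    V = nuclear_attraction(basis, Z, centers)
    H = T + V
    eri = eri_tensor(basis)

    # symmetric orthogonalization with linear-dependence pruning
    sval, svec = np.linalg.eigh(S)
    keep = sval > 1e-7
    X = svec[:, keep] / np.sqrt(sval[keep])

    E_nuc = 0.0
    for i in range(len(Z)):
        for j in range(i):
            E_nuc += Z[i] * Z[j] / np.linalg.norm(centers[i] - centers[j])

    def fock(D):
        J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
        return H + J - 0.5 * K

    # core guess
    Hp = X.T @ H @ X
    e, c = np.linalg.eigh(Hp)
    C = X @ c
    D = 2.0 * C[:, :nocc] @ C[:, :nocc].T

    diis_F, diis_err = [], []
    E_old = 0.0
    for it in range(max_iter):
        F = fock(D)
        err = F @ D @ S - S @ D @ F
        diis_F.append(F)
        diis_err.append(err)
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            n = len(diis_F)
            B = -np.ones((n + 1, n + 1))
            B[-1, -1] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = np.einsum("pq,pq->", diis_err[i], diis_err[j])
            rhs = np.zeros(n + 1)
            rhs[-1] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:n]
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
            except np.linalg.LinAlgError:
                pass
        e, c = np.linalg.eigh(X.T @ F @ X)
        C = X @ c
        D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        E = 0.5 * np.einsum("pq,pq->", D_new, H + fock(D_new)) + E_nuc
        dE = abs(E - E_old)
        drms = np.sqrt(np.mean((D_new - D) ** 2))
        if verbose:
            print(f"  SCF iter {it:2d}  E = {E:.10f}  dE = {dE:.2e}  dD = {drms:.2e}")
        D = D_new
        E_old = E
        if dE < conv and drms < conv * 10:
            break
    else:
        raise RuntimeError("SCF did not converge")

    return SCFResult(E=E, E_nuc=E_nuc, C=C, eps=e, D=D, nocc=nocc,
                     S=S, eri=eri, basis=basis, nelec=nelec)


def mp2_density(res: SCFResult):
    """Unrelaxed (response-free) MP2 one-particle density in the AO basis.

    Returns (D_mp2_ao, E_mp2_correlation)."""
    C, eps, nocc = res.C, res.eps, res.nocc
    nmo = C.shape[1]
    nvir = nmo - nocc
    Co, Cv = C[:, :nocc], C[:, nocc:]
    # (ia|jb)
    tmp = np.einsum("pqrs,pi->iqrs", res.eri, Co, optimize=True)
    tmp = np.einsum("iqrs,qa->iars", tmp, Cv, optimize=True)
    tmp = np.einsum("iars,rj->iajs", tmp, Co, optimize=True)
    ovov = np.einsum("iajs,sb->iajb", tmp, Cv, optimize=True)
    eo, ev = eps[:nocc], eps[nocc:]
    denom = (eo[:, None, None, None] - ev[None, :, None, None]
             + eo[None, None, :, None] - ev[None, None, None, :])
    t2 = ovov / denom                                    # t[i,a,j,b]
    E2 = float(np.einsum("iajb,iajb->", t2, 2.0 * ovov)
               - np.einsum("iajb,ibja->", t2, ovov))
    # correlation corrections (spatial-orbital, closed shell)
    Dvv = 2.0 * (2.0 * np.einsum("iajc,ibjc->ab", t2, t2, optimize=True)
                 - np.einsum("iajc,jbic->ab", t2, t2, optimize=True))
    Doo = -2.0 * (2.0 * np.einsum("iakb,jakb->ij", t2, t2, optimize=True)
                  - np.einsum("iakb,kajb->ij", t2, t2, optimize=True))
    Dmo = np.zeros((nmo, nmo))
    Dmo[:nocc, :nocc] = np.diag(2.0 * np.ones(nocc)) + Doo
    Dmo[nocc:, nocc:] = Dvv
    Dao = C @ Dmo @ C.T
    return Dao, E2


def wavefunction_from_scf(geometry, shells, res: SCFResult,
                          density: str = "SCF") -> WavefunctionData:
    if density.upper() == "SCF":
        dm = res.D
    elif density.upper() == "MP2":
        dm, _ = mp2_density(res)
    else:
        raise ValueError(f"backend provides SCF or MP2 densities, not {density}")
    return WavefunctionData(geometry, list(shells), dm, density.upper(),
                            n_electrons=res.nelec)
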