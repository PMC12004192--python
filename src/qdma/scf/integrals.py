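"""Molecular integrals for the minimal SCF backend.

McMurchie-Davidson scheme: Cartesian Gaussian pairs are expanded in
Hermite Gaussians (E coefficients); Coulomb-type integrals contract the
Hermite expansions with the Boys-function-derived R tensor.  Overlap,
kinetic and multipole one-electron integrals reuse the closed-form even
Gaussian moments from the main engine.

Everything is vectorized over primitive pairs/quartets; shell loops stay
in Python.  This is a reference implementation for generating modest
fixture densities, not a production SCF.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gamma

from .._gauss import CART_ORDER, ShellBasis, ncart


# ----------------------------------------------------------------------
# Boys function
# ----------------------------------------------------------------------

def boys(mmax: int, T: np.ndarray) -> np.ndarray:
    """F_m(T) for m = 0..mmax over an array of T; shape (mmax+1,) + T.shape."""
    T = np.asarray(T, dtype=float)
    out = np.empty((mmax + 1,) + T.shape)
    small = T < 1e-13
    Ts = np.where(small, 1.0, T)
    m = mmax
    Fm = np.where(
        small, 1.0 / (2 * m + 1),
        0.5 * gamma(m + 0.5) * gammainc(m + 0.5, Ts) / Ts ** (m + 0.5))
    out[mmax] = Fm
    expT = np.exp(-T)
    for m in range(mmax - 1, -1, -1):
        out[m] = np.where(small, 1.0 / (2 * m + 1),
                          (2.0 * T * out[m + 1] + expT) / (2 * m + 1))
    return out


# ----------------------------------------------------------------------
# Hermite expansion coefficients
# ----------------------------------------------------------------------

def e_coeffs(la: int, lb: int, PA, PB, p) -> np.ndarray:
    """E[t, i, j] per dimension, vectorized over primitive pairs.

    PA, PB, p are arrays over pairs; returns (npair, la+1, lb+1, la+lb+1).
    Gaussian-product prefactor NOT included.
    """
    PA = np.asarray(PA, float)
    n = PA.shape[0]
    L = la + lb
    E = np.zeros((n, la + 1, lb + 1, L + 2))  # one spare t slot
    E[:, 0, 0, 0] = 1.0
    inv2p = 1.0 / (2.0 * p)
    for i in range(la):
        for t in range(i + 2):
            E[:, i + 1, 0, t] = (
                (inv2p * E[:, i, 0, t - 1] if t > 0 else 0.0)
                + PA * E[:, i, 0, t]
                + (t + 1) * E[:, i, 0, t + 1])
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 1 + 1):
                E[:, i, j + 1, t] = (
                    (inv2p * E[:, i, j, t - 1] if t > 0 else 0.0)
                    + PB * E[:, i, j, t]
                    + (t + 1) * E[:, i, j, t + 1])
    return E[:, :, :, : L + 1]


def pair_hermite(sa, sb):
    """Per-dimension E tensors and pair data for a shell pair.

    Returns dict with p (npair,), P (npair,3), K (npair,), w (npair,)
    and Eb (npair, ncart_a, ncart_b, t, u, v).
    """
    al = sa.alphas[:, None]
    be = sb.alphas[None, :]
    p = (al + be).ravel()
    w = (sa.wnorm[:, None] * sb.wnorm[None, :]).ravel()
    P = ((al[..., None] * sa.center + be[..., None] * sb.center)
         / (al + be)[..., None]).reshape(-1, 3)
    mu = (al * be / (al + be)).ravel()
    AB = sa.center - sb.center
    K = np.exp(-mu * float(AB @ AB))
    Es = [e_coeffs(sa.l, sb.l, P[:, d] - sa.center[d], P[:, d] - sb.center[d], p)
          for d in range(3)]
    ea, eb = sa.exps, sb.exps
    L = sa.l + sb.l
    npair = p.size
    Eb = np.empty((npair, len(ea), len(eb), L + 1, L + 1, L + 1))
    for a, (ix, iy, iz) in enumerate(ea):
        for b, (jx, jy, jz) in enumerate(eb):
            Eb[:, a, b] = (Es[0][:, ix, jx, :, None, None]
                           * Es[1][:, iy, jy, None, :, None]
                           * Es[2][:, iz, jz, None, None, :])
    return dict(p=p, P=P, K=K, w=w, Eb=Eb, L=L)


def r_tensor(L: int, alpha: np.ndarray, RPQ: np.ndarray) -> np.ndarray:
    """Hermite Coulomb tensor R_{tuv} (n=0), shape (nq, L+1, L+1, L+1)."""
    nq = alpha.shape[0]
    T = alpha * np.einsum("qi,qi->q", RPQ, RPQ)
    F = boys(L, T)                       # (L+1, nq)
    base = ((-2.0 * alpha) ** np.arange(L + 1)[:, None]) * F  # R^n_000
    R = np.zeros((L + 1, nq, L + 1, L + 1, L + 1))
    R[:, :, 0, 0, 0] = base
    x, y, z = RPQ[:, 0], RPQ[:, 1], RPQ[:, 2]
    for n in range(L - 1, -1, -1):
        for t in range(L - n + 1):
            for u in range(L - n - t + 1):
                for v in range(L - n - t - u + 1):
                    if t + u + v == 0 or t + u + v > L - n:
                        continue
                    if t > 0:
                        val = x * R[n + 1, :, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R[n + 1, :, t - 2, u, v]
                    elif u > 0:
                        val = y * R[n + 1, :, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R[n + 1, :, t, u - 2, v]
                    else:
                        val = z * R[n + 1, :, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R[n + 1, :, t, u, v - 2]
                    R[n, :, t, u, v] = val
    return R[0]


# ----------------------------------------------------------------------
# one-electron matrices
# ----------------------------------------------------------------------

def overlap_kinetic(basis: ShellBasis):
    """S and T in the AO basis (pure transforms applied)."""
    from .._gauss import dim_moment_table
    nao = basis.nao
    S = np.zeros((nao, nao))
    Tm = np.zeros((nao, nao))
    for a, sa in enumerate(basis.shells):
        for b, sb in enumerate(basis.shells):
            if b > a:
                continue
            Sblk = np.zeros((ncart(sa.l), ncart(sb.l)))
            Tblk = np.zeros_like(Sblk)
            for ia, al in enumerate(sa.alphas):
                for ib, be in enumerate(sb.alphas):
                    w = sa.wnorm[ia] * sb.wnorm[ib]
                    tabs = [dim_moment_table(
                        sa.center[d], sb.center[d], sb.center[d], al, be,
                        sa.l, sb.l + 2, 0)[:, :, 0] for d in range(3)]
                    for ca, (ix, iy, iz) in enumerate(sa.exps):
                        for cb, (jx, jy, jz) in enumerate(sb.exps):
                            s = tabs[0][ix, jx] * tabs[1][iy, jy] * tabs[2][iz, jz]
                            Sblk[ca, cb] += w * s
                            t = 0.0
                            for d, (ja, jb) in enumerate(
                                    [(ix, jx), (iy, jy), (iz, jz)]):
                                rest = [tabs[e][[ix, iy, iz][e], [jx, jy, jz][e]]
                                        for e in range(3) if e != d]
                                m2 = tabs[d][ja, jb + 2]
                                m0 = tabs[d][ja, jb]
                                mm2 = tabs[d][ja, jb - 2] if jb >= 2 else 0.0
                                t += (-0.5) * (jb * (jb - 1) * mm2
                                               - 2 * be * (2 * jb + 1) * m0
                                               + 4 * be * be * m2) * np.prod(rest)
                            Tblk[ca, cb] += w * t
            ra = slice(sa.ao_start, sa.ao_start + sa.nao)
            rb = slice(sb.ao_start, sb.ao_start + sb.nao)
            S[ra, rb] = sa.T @ Sblk @ sb.T.T
            Tm[ra, rb] = sa.T @ Tblk @ sb.T.T
            if a != b:
                S[rb, ra] = S[ra, rb].T
                Tm[rb, ra] = Tm[ra, rb].T
    return S, Tm


def nuclear_attraction(basis: ShellBasis, charges, centers_bohr):
    """V_ab = -sum_C Z_C <a| 1/|r - C| |b>."""
    nao = basis.nao
    V = np.zeros((nao, nao))
    charges = np.asarray(charges, float)
    centers = np.asarray(centers_bohr, float)
    for a, sa in enumerate(basis.shells):
        for b, sb in enumerate(basis.shells):
            if b > a:
                continue
            ph = pair_hermite(sa, sb)
            L = ph["L"]
            npair = ph["p"].size
            blk = np.zeros((npair, ncart(sa.l), ncart(sb.l)))
            for Z, C in zip(charges, centers):
                R = r_tensor(L, ph["p"], ph["P"] - C)       # (npair, ...)
                blk += -Z * np.einsum("qabtuv,qtuv->qab", ph["Eb"], R)
            pref = 2.0 * np.pi / ph["p"] * ph["K"] * ph["w"]
            cart = np.einsum("q,qab->ab", pref, blk)
            ra = slice(sa.ao_start, sa.ao_start + sa.nao)
            rb = slice(sb.ao_start, sb.ao_start + sb.nao)
            V[ra, rb] = sa.T @ cart @ sb.T.T
            if a != b:
                V[rb, ra] = V[ra, rb].T
    return V


# ----------------------------------------------------------------------
# two-electron integrals
# ----------------------------------------------------------------------

def eri_tensor(basis: ShellBasis, screen: float = 1e-12) -> np.ndarray:
    """Full (ab|cd) tensor in the AO basis (chemists' notation)."""
    nao = basis.nao
    shells = basis.shells
    ns = len(shells)
    pairs = []
    for a in range(ns):
        for b in range(a + 1):
            ph = pair_hermite(shells[a], shells[b])
            # fold weights & K into Eb
            ph["Ebw"] = ph["Eb"] * (ph["w"] * ph["K"])[:, None, None,
                                                       None, None, None]
            pairs.append((a, b, ph))
    eri = np.zeros((nao, nao, nao, nao))
    TWO_PI_52 = 2.0 * np.pi ** 2.5

    def put(block, sa, sb, sc, sd):
        ra = slice(sa.ao_start, sa.ao_start + sa.nao)
        rb = slice(sb.ao_start, sb.ao_start + sb.nao)
        rc = slice(sc.ao_start, sc.ao_start + sc.nao)
        rd = slice(sd.ao_start, sd.ao_start + sd.nao)
        eri[ra, rb, rc, rd] = block
        eri[rb, ra, rc, rd] = block.transpose(1, 0, 2, 3)
        eri[ra, rb, rd, rc] = block.transpose(0, 1, 3, 2)
        eri[rb, ra, rd, rc] = block.transpose(1, 0, 3, 2)
        eri[rc, rd, ra, rb] = block.transpose(2, 3, 0, 1)
        eri[rd, rc, ra, rb] = block.transpose(3, 2, 0, 1)
        eri[rc, rd, rb, ra] = block.transpose(2, 3, 1, 0)
        eri[rd, rc, rb, ra] = block.transpose(3, 2, 1, 0)

    for ipair, (a, b, phb) in enumerate(pairs):
        sa, sb = shells[a], shells[b]
        for (c, d, phk) in pairs[: ipair + 1]:
            sc, sd = shells[c], shells[d]
            Lb, Lk = phb["L"], phk["L"]
            L = Lb + Lk
            p = phb["p"][:, None]
            q = phk["p"][None, :]
            alpha = (p * q / (p + q)).ravel()
            RPQ = (phb["P"][:, None, :] - phk["P"][None, :, :]).reshape(-1, 3)
            R = r_tensor(L, alpha, RPQ).reshape(
                phb["p"].size, phk["p"].size, L + 1, L + 1, L + 1)
            pref = (TWO_PI_52 / (p * q * np.sqrt(p + q)))
            # sign (-1)^(tau+ups+phi) on the ket side
            sgn = (-1.0) ** (np.arange(Lk + 1))
            Ekm = phk["Ebw"] * (sgn[:, None, None] * sgn[None, :, None]
                                * sgn[None, None, :])
            # G[qb, qk, a, b, tau, ups, phi] gathers R[t+tau, u+ups, v+phi]
            G = np.zeros((phb["p"].size, phk["p"].size,
                          ncart(sa.l), ncart(sb.l), Lk + 1, Lk + 1, Lk + 1))
            for t in range(Lb + 1):
                for u in range(Lb + 1 - t):
                    for v in range(Lb + 1 - t - u):
                        Rsub = R[:, :, t: t + Lk + 1, u: u + Lk + 1,
                                 v: v + Lk + 1]
                        G += (phb["Ebw"][:, None, :, :, t, u, v]
                              [:, :, :, :, None, None, None] * Rsub[
                                  :, :, None, None, :, :, :])
            cart = np.einsum("xyabtuv,ycdtuv,xy->abcd", G, Ekm,
                             pref, optimize=True)
            blk = np.einsum("am,mncd->ancd", sa.T, cart)
            blk = np.einsum("bn,ancd->abcd", sb.T, blk)
            blk = np.einsum("co,abod->abcd", sc.T, blk)
            blk = np.einsum("dp,abcp->abcd", sd.T, blk)
            put(blk, sa, sb, sc, sd)
    return eri
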