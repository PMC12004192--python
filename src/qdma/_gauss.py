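"""Gaussian-basis machinery: AO expansion, overlap and moment integrals.

All integrals are one-electron moments of real regular solid harmonics
over primitive Gaussian pairs, evaluated in closed form through the
Gaussian product theorem and 1D even moments

    int u^n exp(-p u^2) du = (n-1)!! / (2p)^(n/2) * sqrt(pi/p)   (n even).

Internally everything is in Bohr and atomic units; geometry positions
arrive in Angstrom and are converted once.

AO conventions (the formatted-checkpoint dialect):
  * Cartesian component order
      p : x, y, z
      d : xx, yy, zz, xy, xz, yz
      f : xxx, yyy, zzz, xyy, xxy, xxz, xzz, yzz, yyz, xyz
      g : zzzz, yzzz, yyzz, yyyz, yyyy, xzzz, xyzz, xyyz, xyyy,
          xxzz, xxyz, xxyy, xxxz, xxxy, xxxx
  * pure (spherical) order: m = 0, +1, -1, +2, -2, ... (cosine = +m).
  * Contraction coefficients multiply primitives normalized to the
    axial Cartesian component: N(a, l) = (2a/pi)^(3/4) (4a)^(l/2) / sqrt((2l-1)!!).
    Cartesian cross components share that radial normalization; pure
    components are unit-normalized solid-harmonic Gaussians.
"""
from __future__ import annotations

from functools import lru_cache
from math import comb, pi, sqrt

import numpy as np

from . import _solid
from .multipole_math import BOHR_ANGSTROM

MAX_L = 4  # engine maximum shell angular momentum (g)

CART_ORDER = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
    3: [(3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 2, 0), (2, 1, 0),
        (2, 0, 1), (1, 0, 2), (0, 1, 2), (0, 2, 1), (1, 1, 1)],
    4: [(0, 0, 4), (0, 1, 3), (0, 2, 2), (0, 3, 1), (0, 4, 0),
        (1, 0, 3), (1, 1, 2), (1, 2, 1), (1, 3, 0), (2, 0, 2),
        (2, 1, 1), (2, 2, 0), (3, 0, 1), (3, 1, 0), (4, 0, 0)],
}


def ncart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def nao_shell(l: int, pure: bool) -> int:
    return 2 * l + 1 if pure else ncart(l)


def double_factorial(n: int) -> int:
    if n <= 0:
        return 1
    out = 1
    while n > 0:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Normalization of the axial Cartesian primitive x^l exp(-a r^2)."""
    return ((2 * alpha / pi) ** 0.75 * (4 * alpha) ** (l / 2.0)
            / sqrt(double_factorial(2 * l - 1)))


@lru_cache(maxsize=None)
def _gauss_even_moments(nmax: int):
    """Coefficients c[n] with int u^n e^{-p u^2} du = c[n] p^{-(n+1)/2} (even n)."""
    c = np.zeros(nmax + 1)
    for n in range(0, nmax + 1, 2):
        c[n] = double_factorial(n - 1) / 2.0 ** (n // 2) * sqrt(pi)
    return c


def gauss_moments(p: float, nmax: int) -> np.ndarray:
    """G[n] = int u^n exp(-p u^2) du for n = 0..nmax (odd entries zero)."""
    c = _gauss_even_moments(nmax)
    n = np.arange(nmax + 1)
    with np.errstate(divide="ignore"):
        return np.where(c > 0, c * p ** (-(n + 1) / 2.0), 0.0)


@lru_cache(maxsize=None)
def _binom_cache(n: int):
    return np.array([[comb(i, j) if j <= i else 0 for j in range(n + 1)]
                     for i in range(n + 1)], dtype=float)


def _shift_weights(dist: float, nmax: int, smax: int) -> np.ndarray:
    """W[n, s] = C(n, s) * dist^(n-s): expansion of (x - C)^n about P."""
    B = _binom_cache(max(nmax, smax))[: nmax + 1, : smax + 1]
    pw = np.ones(nmax + 1)
    for i in range(1, nmax + 1):
        pw[i] = pw[i - 1] * dist
    n = np.arange(nmax + 1)[:, None]
    s = np.arange(smax + 1)[None, :]
    with np.errstate(invalid="ignore"):
        P = np.where(n - s >= 0, pw[np.clip(n - s, 0, nmax)], 0.0)
    return B * P


def dim_moment_table(Ax: float, Bx: float, Ox: float, alpha: float, beta: float,
                     na_max: int, nb_max: int, n_max: int) -> np.ndarray:
    """I[na, nb, n] = int (x-Ax)^na (x-Bx)^nb (x-Ox)^n exp(-a(x-Ax)^2 - b(x-Bx)^2) dx."""
    p = alpha + beta
    Px = (alpha * Ax + beta * Bx) / p
    K = np.exp(-alpha * beta / p * (Ax - Bx) ** 2)
    G = gauss_moments(p, na_max + nb_max + n_max)
    WA = _shift_weights(Px - Ax, na_max, na_max)
    WB = _shift_weights(Px - Bx, nb_max, nb_max)
    WO = _shift_weights(Px - Ox, n_max, n_max)
    # I[na,nb,n] = sum_{s,t,u} WA[na,s] WB[nb,t] WO[n,u] G[s+t+u]
    s = np.arange(na_max + 1)
    t = np.arange(nb_max + 1)
    u = np.arange(n_max + 1)
    GG = G[s[:, None, None] + t[None, :, None] + u[None, None, :]]
    return K * np.einsum("as,bt,nu,stu->abn", WA, WB, WO, GG, optimize=True)


@lru_cache(maxsize=None)
def _pure_norm_const(l: int) -> float:
    """Alpha-independent constant C_l with C_l * N(a,l) * R_lk(r) e^{-a r^2} unit-normalized."""
    poly = _solid.real_poly_table(l)[_solid.offset(l)]  # R_l0
    G = gauss_moments(2.0, 2 * l)
    s = 0.0
    for (i1, j1, k1), c1 in poly.items():
        for (i2, j2, k2), c2 in poly.items():
            s += c1 * c2 * G[i1 + i2] * G[j1 + j2] * G[k1 + k2]
    return 1.0 / (primitive_norm(1.0, l) * sqrt(s))


@lru_cache(maxsize=None)
def _pure_transform(l: int) -> np.ndarray:
    """T[k, m] mapping Cartesian monomial components to pure components.

    Row k is the real solid harmonic (order 0, 1c, 1s, ...) expressed in
    the CART_ORDER monomials, scaled by the pure normalization constant.
    """
    monos = CART_ORDER[l]
    T = np.zeros((2 * l + 1, len(monos)))
    base = _solid.offset(l)
    polys = _solid.real_poly_table(l)
    C = _pure_norm_const(l)
    for k in range(2 * l + 1):
        for mono, c in polys[base + k].items():
            T[k, monos.index(mono)] = C * c
    return T


class ShellInfo:
    """Expanded view of one contracted shell (positions in Bohr)."""

    __slots__ = ("center", "l", "pure", "alphas", "coefs", "wnorm", "T",
                 "exps", "ao_start", "nao")

    def __init__(self, center_bohr, l, pure, alphas, coefs, ao_start):
        if l > MAX_L:
            raise ValueError(f"angular momentum l={l} exceeds engine maximum {MAX_L}")
        self.center = np.asarray(center_bohr, dtype=float)
        self.l = int(l)
        self.pure = bool(pure) and l >= 2
        self.alphas = np.asarray(alphas, dtype=float)
        self.coefs = np.asarray(coefs, dtype=float)
        if np.any(self.alphas <= 0):
            raise ValueError("primitive exponents must be positive")
        self.wnorm = self.coefs * np.array(
            [primitive_norm(a, self.l) for a in self.alphas])
        self.T = (_pure_transform(self.l) if self.pure
                  else np.eye(ncart(self.l)))
        self.exps = np.array(CART_ORDER[self.l])  # (ncart, 3)
        self.ao_start = ao_start
        self.nao = nao_shell(self.l, self.pure)


class ShellBasis:
    """Geometry + contracted shells expanded into integral-ready form."""

    def __init__(self, geometry, shells):
        self.geometry = geometry
        centers = [np.asarray(a.position, dtype=float) / BOHR_ANGSTROM
                   for a in geometry.atoms]
        self.shells = []
        ao = 0
        for sh in shells:
            info = ShellInfo(centers[sh.center], sh.l, sh.pure,
                             [p[0] for p in sh.primitives],
                             [p[1] for p in sh.primitives], ao)
            self.shells.append(info)
            ao += info.nao
        self.nao = ao

    # ------------------------------------------------------------------
    def _pair_cart_moments(self, sa: ShellInfo, sb: ShellInfo, ia: int, ib: int,
                           origin_bohr, comp_polys) -> np.ndarray:
        """M[ma, mb, c]: moments of one primitive pair over Cartesian components."""
        A, B = sa.center, sb.center
        al, be = sa.alphas[ia], sb.alphas[ib]
        deg = max((max(i, j, k) for p in comp_polys for (i, j, k) in p),
                  default=0)
        tabs = [dim_moment_table(A[d], B[d], origin_bohr[d], al, be,
                                 sa.l, sb.l, deg) for d in range(3)]
        ea, eb = sa.exps, sb.exps
        M = np.zeros((len(ea), len(eb), len(comp_polys)))
        for c, poly in enumerate(comp_polys):
            acc = np.zeros((len(ea), len(eb)))
            for (u, v, w), coeff in poly.items():
                acc += coeff * (tabs[0][ea[:, 0]][:, eb[:, 0], u]
                                * tabs[1][ea[:, 1]][:, eb[:, 1], v]
                                * tabs[2][ea[:, 2]][:, eb[:, 2], w])
            M[:, :, c] = acc
        return M

    def moment_matrices(self, origin_ang, lmax: int) -> np.ndarray:
        """S_c[mu, nu] = <mu| R_c(r - origin) |nu> for all components c <= lmax.

        `origin_ang` in Angstrom; results in e*a0^l per rank.
        Component 0 is the overlap matrix.
        """
        origin = np.asarray(origin_ang, dtype=float) / BOHR_ANGSTROM
        comp_polys = _solid.real_poly_table(lmax)[: _solid.n_components(lmax)]
        out = np.zeros((_solid.n_components(lmax), self.nao, self.nao))
        ns = len(self.shells)
        for a in range(ns):
            sa = self.shells[a]
            for b in range(a + 1):
                sb = self.shells[b]
                blk = np.zeros((ncart(sa.l), ncart(sb.l), len(comp_polys)))
                for ia in range(len(sa.alphas)):
                    for ib in range(len(sb.alphas)):
                        w = sa.wnorm[ia] * sb.wnorm[ib]
                        blk += w * self._pair_cart_moments(
                            sa, sb, ia, ib, origin, comp_polys)
                aoblk = np.einsum("am,mnc,bn->cab", sa.T, blk, sb.T)
                ra = slice(sa.ao_start, sa.ao_start + sa.nao)
                rb = slice(sb.ao_start, sb.ao_start + sb.nao)
                out[:, ra, rb] = aoblk
                if a != b:
                    out[:, rb, ra] = aoblk.transpose(0, 2, 1)
        return out

    def overlap(self) -> np.ndarray:
        return self.moment_matrices(np.zeros(3), 0)[0]

    # ------------------------------------------------------------------
    def ao_values(self, points_bohr: np.ndarray) -> np.ndarray:
        """AO values at grid points (npts, 3) in Bohr -> (npts, nao)."""
        pts = np.asarray(points_bohr, dtype=float)
        out = np.zeros((pts.shape[0], self.nao))
        for sh in self.shells:
            d = pts - sh.center
            r2 = np.einsum("pi,pi->p", d, d)
            rad = np.zeros(pts.shape[0])
            for a, w in zip(sh.alphas, sh.wnorm):
                rad += w * np.exp(-a * r2)
            mono = np.ones((pts.shape[0], ncart(sh.l)))
            for m, (i, j, k) in enumerate(CART_ORDER[sh.l]):
                mono[:, m] = d[:, 0] ** i * d[:, 1] ** j * d[:, 2] ** k
            out[:, sh.ao_start: sh.ao_start + sh.nao] = (
                rad[:, None] * (mono @ sh.T.T))
        return out
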