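"""Real regular solid harmonics R_lk as explicit polynomials.

Everything downstream (multipole components, translations, pair moments)
is expressed in the Racah-normalized regular solid harmonics, i.e.
R_00 = 1, R_10 = z, R_11c = x, R_20 = (3z^2 - r^2)/2, R_21c = sqrt(3)xz, ...
so that rank-l components carry units e*a0^l directly.

Polynomials are stored as {(i, j, k): coeff} monomial dictionaries; the
tables are generated once per lmax from the complex solid-harmonic
recursions and cached.
"""
from __future__ import annotations

from functools import lru_cache
from math import comb, sqrt

import numpy as np

__all__ = [
    "component_labels",
    "flat_labels",
    "n_components",
    "offset",
    "real_poly_table",
    "eval_real",
    "translation_apply",
]


def n_components(lmax: int) -> int:
    """Total number of real components for ranks 0..lmax: (lmax+1)^2."""
    return (lmax + 1) ** 2


def offset(l: int) -> int:
    """Flat index of component (l, 0); rank l occupies offset(l)..offset(l)+2l."""
    return l * l


def component_labels(l: int) -> list[str]:
    """Labels of the 2l+1 real components of rank l: '0', '1c', '1s', ..."""
    labels = ["0"]
    for m in range(1, l + 1):
        labels += [f"{m}c", f"{m}s"]
    return labels


def flat_labels(lmax: int) -> list[tuple[int, str]]:
    """(l, k) pairs in flat storage order for ranks 0..lmax."""
    out = []
    for l in range(lmax + 1):
        out += [(l, k) for k in component_labels(l)]
    return out


# ----------------------------------------------------------------------
# polynomial helpers (monomial dicts with complex coefficients)
# ----------------------------------------------------------------------

def _pmul(p1: dict, p2: dict) -> dict:
    out: dict = {}
    for (i1, j1, k1), c1 in p1.items():
        for (i2, j2, k2), c2 in p2.items():
            key = (i1 + i2, j1 + j2, k1 + k2)
            out[key] = out.get(key, 0.0) + c1 * c2
    return out

def _padd(p1: dict, p2: dict, s: complex = 1.0) -> dict:
    out = dict(p1)
    for key, c in p2.items():
        out[key] = out.get(key, 0.0) + s * c
    return {k: v for k, v in out.items() if v != 0}

def _pscale(p: dict, s: complex) -> dict:
    return {k: s * c for k, c in p.items()}


_X = {(1, 0, 0): 1.0}
_Y = {(0, 1, 0): 1.0}
_Z = {(0, 0, 1): 1.0}
_R2 = {(2, 0, 0): 1.0, (0, 2, 0): 1.0, (0, 0, 2): 1.0}
_XPIY = {(1, 0, 0): 1.0, (0, 1, 0): 1.0j}  # x + i y


@lru_cache(maxsize=None)
def _complex_table(lmax: int) -> dict:
    """Complex Racah solid harmonics R_l^m for 0 <= l <= lmax, -l <= m <= l."""
    R = {(0, 0): {(0, 0, 0): 1.0 + 0.0j}}
    for l in range(lmax):
        # diagonal: R_{l+1}^{l+1} = -sqrt((2l+1)/(2l+2)) (x+iy) R_l^l
        R[(l + 1, l + 1)] = _pscale(
            _pmul(_XPIY, R[(l, l)]), -sqrt((2 * l + 1) / (2 * l + 2))
        )
        # vertical: R_{l+1}^m from R_l^m and R_{l-1}^m
        for m in range(0, l + 1):
            num = _pscale(_pmul(_Z, R[(l, m)]), float(2 * l + 1))
            if l - 1 >= abs(m):
                num = _padd(num, _pmul(_R2, R[(l - 1, m)]),
                            -sqrt((l + m) * (l - m)))
            R[(l + 1, m)] = _pscale(num, 1.0 / sqrt((l + 1 + m) * (l + 1 - m)))
        # negative m by conjugation: R_l^{-m} = (-1)^m conj(R_l^m)
        for m in range(1, l + 2):
            R[(l + 1, -m)] = {
                key: (-1) ** m * np.conj(c) for key, c in R[(l + 1, m)].items()
            }
    return R


@lru_cache(maxsize=None)
def real_poly_table(lmax: int) -> list[dict]:
    """Real-component polynomials in flat order (l=0..lmax; k=0,1c,1s,...).

    R_{l,mc} = (-1)^m sqrt(2) Re R_l^m ; R_{l,ms} = (-1)^m sqrt(2) Im R_l^m.
    """
    C = _complex_table(lmax)
    polys = []
    for l in range(lmax + 1):
        p0 = {k: c.real for k, c in C[(l, 0)].items() if c.real != 0}
        polys.append(p0)
        for m in range(1, l + 1):
            s = (-1) ** m * sqrt(2.0)
            pc = {k: s * c.real for k, c in C[(l, m)].items() if c.real != 0}
            ps = {k: s * c.imag for k, c in C[(l, m)].items() if c.imag != 0}
            polys += [pc, ps]
    return polys


def eval_real(points: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate all real R_lk at `points` (..., 3); returns (..., (lmax+1)^2).

    Positions must already be in the length unit the components are wanted
    in (Bohr for e*a0^l moments).
    """
    pts = np.asarray(points, dtype=float)
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    polys = real_poly_table(lmax)
    out = np.empty(pts.shape[:-1] + (n_components(lmax),))
    # cache monomial powers
    maxpow = lmax
    xp = [np.ones_like(x)]
    yp = [np.ones_like(y)]
    zp = [np.ones_like(z)]
    for _ in range(maxpow):
        xp.append(xp[-1] * x)
        yp.append(yp[-1] * y)
        zp.append(zp[-1] * z)
    for idx, poly in enumerate(polys):
        acc = np.zeros_like(x)
        for (i, j, k), c in poly.items():
            acc += c * xp[i] * yp[j] * zp[k]
        out[..., idx] = acc
    return out


# ----------------------------------------------------------------------
# translation (regular-solid-harmonic addition theorem)
# ----------------------------------------------------------------------

def _real_to_complex(q: np.ndarray, lmax: int) -> list[np.ndarray]:
    """Per-rank complex component vectors c[l][m + l], m = -l..l."""
    out = []
    inv = 1.0 / sqrt(2.0)
    for l in range(lmax + 1):
        base = offset(l)
        c = np.zeros(2 * l + 1, dtype=complex)
        c[l] = q[base]
        for m in range(1, l + 1):
            qc = q[base + 2 * m - 1]
            qs = q[base + 2 * m]
            c[l + m] = (-1) ** m * (qc + 1j * qs) * inv
            c[l - m] = (qc - 1j * qs) * inv
        out.append(c)
    return out


def _complex_to_real(c: list[np.ndarray], lmax: int) -> np.ndarray:
    q = np.zeros(n_components(lmax))
    for l in range(lmax + 1):
        base = offset(l)
        q[base] = c[l][l].real
        for m in range(1, l + 1):
            z = (-1) ** m * sqrt(2.0) * c[l][l + m]
            q[base + 2 * m - 1] = z.real
            q[base + 2 * m] = z.imag
    return q


def translation_apply(q: np.ndarray, lmax: int, disp_bohr: np.ndarray) -> np.ndarray:
    """Moments about a new origin o given moments `q` about p.

    `disp_bohr` is (p - o) in Bohr.  Implements the addition theorem
      R_L^M(a + b) = sum_{l,m} sqrt(C(L+M, l+m) C(L-M, l-m)) R_l^m(a) R_{L-l}^{M-m}(b)
    applied to Q_L^M(o) = sum_i q_i R_L^M((r_i - p) + (p - o)).
    """
    disp = np.asarray(disp_bohr, dtype=float)
    if np.allclose(disp, 0.0):
        return q.copy()
    C = _complex_table(lmax)
    x, y, z = disp

    def ev(poly):
        return sum(c * x**i * y**j * z**k for (i, j, k), c in poly.items())

    Rd = {(l, m): ev(C[(l, m)]) for l in range(lmax + 1) for m in range(-l, l + 1)}
    cin = _real_to_complex(q, lmax)
    cout = [np.zeros(2 * L + 1, dtype=complex) for L in range(lmax + 1)]
    for L in range(lmax + 1):
        for M in range(-L, L + 1):
            acc = 0.0 + 0.0j
            for l in range(L + 1):
                for m in range(-l, l + 1):
                    mm = M - m
                    if abs(mm) > L - l:
                        continue
                    w = sqrt(comb(L + M, l + m) * comb(L - M, l - m))
                    acc += w * cin[l][l + m] * Rd[(L - l, mm)]
            cout[L][L + M] = acc
    return _complex_to_real(cout, lmax)
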