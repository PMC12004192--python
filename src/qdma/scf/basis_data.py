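"""Published Gaussian basis sets used by the fixture backend.

Exponents and contraction coefficients are the standard literature
values (Hehre-Stewart-Pople STO-3G; Pople 6-31G / 6-311G families with
the usual diffuse and polarization exponents).  Contractions are
renormalized to unit self-overlap when shells are built, as electronic
structure programs do.
"""
from __future__ import annotations

import numpy as np

from ..io_formats import GaussianShell, Geometry

# STO-3G: zeta-scaled least-squares Gaussian expansions of Slater functions
_STO3G_1S = [(2.227660584, 0.154328967),
             (0.405771156, 0.535328142),
             (0.109818000, 0.444634542)]
_STO3G_2SP = [(0.994203, -0.09996723, 0.15591627),
              (0.231031, 0.39951283, 0.60768372),
              (0.0751386, 0.70011547, 0.39195739)]
_STO3G_ZETA = {  # (zeta_1s, zeta_2sp)
    "H": (1.24, None), "C": (5.67, 1.72), "N": (6.67, 1.95), "O": (7.66, 2.25),
}


def _sto3g(symbol):
    z1, z2 = _STO3G_ZETA[symbol]
    out = [("s", [(a * z1 ** 2, c) for a, c in _STO3G_1S])]
    if z2 is not None:
        out.append(("sp", [(a * z2 ** 2, cs, cp)
                           for a, cs, cp in _STO3G_2SP]))
    return out


_BASIS = {
    "sto-3g": {s: _sto3g(s) for s in _STO3G_ZETA},
    "6-31g": {
        "H": [("s", [(18.7311370, 0.03349460), (2.8253937, 0.23472695),
                     (0.6401217, 0.81375733)]),
              ("s", [(0.1612778, 1.0)])],
        "C": [("s", [(3047.5249, 0.0018347), (457.36951, 0.0140373),
                     (103.94869, 0.0688426), (29.210155, 0.2321844),
                     (9.2866630, 0.4679413), (3.1639270, 0.3623120)]),
              ("sp", [(7.8682724, -0.1193324, 0.0689991),
                      (1.8812885, -0.1608542, 0.3164240),
                      (0.5442493, 1.1434564, 0.7443083)]),
              ("sp", [(0.1687144, 1.0, 1.0)])],
        "O": [("s", [(5484.6717, 0.0018311), (825.23495, 0.0139501),
                     (188.04696, 0.0684451), (52.964500, 0.2327143),
                     (16.897570, 0.4701930), (5.7996353, 0.3585209)]),
              ("sp", [(15.539616, -0.1107775, 0.0708743),
                      (3.5999336, -0.1480263, 0.3397528),
                      (1.0137618, 1.1307670, 0.7271586)]),
              ("sp", [(0.2700058, 1.0, 1.0)])],
    },
    "6-311g": {
        "C": [("s", [(4563.2400, 0.00196665), (682.02400, 0.0152306),
                     (154.97300, 0.0761269), (44.455300, 0.2608010),
                     (13.029000, 0.6164620), (1.8277300, 0.2210060)]),
              ("sp", [(20.964200, 0.1146600, 0.0402487),
                      (4.8033100, 0.9199990, 0.2375940),
                      (1.4593300, -0.00303068, 0.8158540)]),
              ("sp", [(0.4834560, 1.0, 1.0)]),
              ("sp", [(0.1455850, 1.0, 1.0)])],
        "O": [("s", [(8588.5000, 0.00189515), (1297.2300, 0.0143859),
                     (299.29600, 0.0707320), (87.377100, 0.2400010),
                     (25.678900, 0.5947970), (3.7400400, 0.2808020)]),
              ("sp", [(42.117500, 0.1138890, 0.0365114),
                      (9.6283700, 0.9208110, 0.2371530),
                      (2.8533200, -0.00327447, 0.8197020)]),
              ("sp", [(0.9056610, 1.0, 1.0)]),
              ("sp", [(0.2556110, 1.0, 1.0)])],
    },
}

# standard augmentation exponents
_DIFFUSE_SP = {"C": 0.0438, "N": 0.0639, "O": 0.0845}
_POL_D = {"C": 0.626, "O": 1.292}          # 6-311G(d)
_POL_D_631 = {"C": 0.8, "N": 0.8, "O": 0.8}  # 6-31G(d)


def available_bases():
    return ["sto-3g", "6-31g", "6-31g+p", "6-311g(d)", "6-311+g(2d)"]


def _element_shells(symbol: str, basis: str):
    b = basis.lower()
    if b == "sto-3g":
        return list(_BASIS["sto-3g"][symbol])
    if b == "6-31g":
        return list(_BASIS["6-31g"][symbol])
    if b == "6-31g+p":
        # 6-31G plus one diffuse p shell on heavy atoms (pi-diffuse augmentation)
        out = list(_BASIS["6-31g"][symbol])
        if symbol in _DIFFUSE_SP:
            out.append(("p", [(_DIFFUSE_SP[symbol], 1.0)]))
        return out
    if b == "6-311g(d)":
        out = list(_BASIS["6-311g"][symbol])
        out.append(("d", [(_POL_D[symbol], 1.0)]))
        return out
    if b == "6-311+g(2d)":
        out = list(_BASIS["6-311g"][symbol])
        if symbol in _DIFFUSE_SP:
            out.append(("sp", [(_DIFFUSE_SP[symbol], 1.0, 1.0)]))
        out.append(("d", [(2.0 * _POL_D[symbol], 1.0)]))
        out.append(("d", [(0.5 * _POL_D[symbol], 1.0)]))
        return out
    raise ValueError(f"unknown basis {basis!r}; available: {available_bases()}")


def _renormalize(shell: GaussianShell) -> GaussianShell:
    """Scale contraction coefficients to unit contracted self-overlap."""
    from .._gauss import ShellBasis

    probe = Geometry.from_arrays(["H"], [[0.0, 0.0, 0.0]])
    trial = GaussianShell(0, shell.l, shell.primitives, shell.pure)
    S = ShellBasis(probe, [trial]).overlap()
    scale = 1.0 / np.sqrt(S[0, 0])
    prims = [(a, c * scale) for a, c in shell.primitives]
    return GaussianShell(shell.center, shell.l, prims, shell.pure)


def build_shells(geometry: Geometry, basis: str):
    """GaussianShell list for `geometry` in the named basis (pure d)."""
    lmap = {"s": 0, "p": 1, "d": 2, "f": 3}
    shells = []
    for iat, atom in enumerate(geometry.atoms):
        for ltok, prims in _element_shells(atom.symbol, basis):
            if ltok == "sp":
                s = GaussianShell(iat, 0, [(p[0], p[1]) for p in prims],
                                  pure=False)
                p_ = GaussianShell(iat, 1, [(p[0], p[2]) for p in prims],
                                   pure=False)
                shells += [_renormalize(s), _renormalize(p_)]
            else:
                sh = GaussianShell(iat, lmap[ltok],
                                   [(p[0], p[1]) for p in prims],
                                   pure=lmap[ltok] >= 2)
                shells.append(_renormalize(sh))
    return shells
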