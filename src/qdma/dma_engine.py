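"""Distributed multipole analysis of a Gaussian-basis electron density.

Every product of two primitive Gaussians is an exact, *finite* multipole
series about the overlap center P = (alpha A + beta B)/(alpha + beta),
terminating at rank lA + lB.  The engine computes those series, assigns
each to the nearest expansion site (distance scaled by per-site radii),
translates the finite series to the site, and accumulates.  Nuclear
charges enter as rank-0 terms on their own sites.  Recombining all site
series about any origin reproduces the direct analytic molecular moments
-- the defining exactness property.

Two allocation paths exist:
  * analytic -- every primitive pair handled as above (exact);
  * grid -- pairs with combined exponent below `exponent_switch` are
    integrated numerically on a Becke-weighted atom-centered grid and
    allocated point-by-point (diffuse density divides more stably
    between sites this way), the rest analytically.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _solid
from ._gauss import ShellBasis, ncart, primitive_norm, dim_moment_table
from .multipole_math import BOHR_ANGSTROM, MultipoleSeries, translate_series

__all__ = [
    "Site", "SiteSet", "PrimitivePairDensity", "DensityDecomposition",
    "assign_site", "pair_multipoles", "iter_primitive_pairs",
    "decompose", "allocate", "distribute_analytic", "distribute_grid",
    "DEFAULT_EXPONENT_SWITCH",
]

#: combined-exponent threshold below which a primitive pair is treated as
#: diffuse on the grid path (a.u.)
DEFAULT_EXPONENT_SWITCH = 4.0

DEFAULT_GRID_SPEC = dict(nrad=80, ntheta=32, nphi=64)


# ----------------------------------------------------------------------
# sites
# ----------------------------------------------------------------------

@dataclass
class Site:
    label: str
    position: np.ndarray            # Angstrom
    radius: float = 1.0             # allocation radius (relative scale)
    max_rank: int | None = None     # None: follow the engine lmax
    is_atom: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("site radius must be positive")
        if self.max_rank is not None and self.max_rank < 0:
            raise ValueError("site max rank must be >= 0")


class SiteSet:
    """Ordered expansion sites: atoms plus optional extra points."""

    def __init__(self, sites):
        self.sites = list(sites)
        if not self.sites:
            raise ValueError("empty site set")
        pos = self.positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-8:
            raise ValueError("site positions must be distinct")

    @classmethod
    def from_geometry(cls, geometry, extra=(), default_radius=1.0,
                      radii_table=None) -> "SiteSet":
        """Atom sites (labels C1, H2, ...) plus `extra` (label, position[,
        radius]) tuples.  `radii_table` maps element symbols to radii."""
        radii_table = radii_table or {}
        sites = []
        counts: dict = {}
        for a in geometry.atoms:
            counts[a.symbol] = counts.get(a.symbol, 0) + 1
            sites.append(Site(f"{a.symbol}{counts[a.symbol]}", a.position,
                              radii_table.get(a.symbol, default_radius),
                              is_atom=True))
        for item in extra:
            label, position = item[0], item[1]
            radius = item[2] if len(item) > 2 else default_radius
            sites.append(Site(label, position, radius, is_atom=False))
        return cls(sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.sites])

    def __len__(self):
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def assign_site(point, sites: SiteSet) -> int:
    """Index of the site minimizing |point - site|/radius (lowest index
    wins exact ties -- deterministic across platforms)."""
    d = np.linalg.norm(sites.positions - np.asarray(point, float), axis=1)
    return int(np.argmin(d / sites.radii))


def _assign_many(points, sites: SiteSet) -> np.ndarray:
    d = np.linalg.norm(points[:, None, :] - sites.positions[None], axis=2)
    return np.argmin(d / sites.radii[None, :], axis=1)


def _becke_site_weights(points, sites: SiteSet, k: int = 3) -> np.ndarray:
    """Smooth fuzzy-cell partition weights w[point, site] (rows sum to 1).

    Becke's cell functions over the expansion sites, with the standard
    size adjustment for unequal site radii; this is how reference DMA
    implementations divide pointwise diffuse density between sites, and
    it removes the discontinuous site hand-off of a hard nearest-site
    rule."""
    from ._grid import _becke_step
    pos = sites.positions
    n = len(sites)
    if n == 1:
        return np.ones((len(points), 1))
    d = np.sqrt(((points[:, None, :] - pos[None]) ** 2).sum(axis=2))
    Rij = np.linalg.norm(pos[:, None] - pos[None], axis=2)
    radii = sites.radii
    P = np.ones((len(points), n))
    for i in range(n):
        for j in range(i + 1, n):
            mu = (d[:, i] - d[:, j]) / Rij[i, j]
            chi = radii[i] / radii[j]
            if chi != 1.0:
                u = (chi - 1.0) / (chi + 1.0)
                a = np.clip(u / (u * u - 1.0), -0.5, 0.5)
                mu = mu + a * (1.0 - mu * mu)
            s = _becke_step(mu, k)
            P[:, i] *= s
            P[:, j] *= 1.0 - s       # step(-mu) = 1 - step(mu)
    return P / P.sum(axis=1)[:, None]


# ----------------------------------------------------------------------
# primitive pairs
# ----------------------------------------------------------------------

@dataclass
class PrimitivePairDensity:
    """One primitive pair's contribution to the density expansion."""

    shell_a: int
    shell_b: int
    alpha: float
    beta: float
    center: np.ndarray        # overlap center P, Angstrom
    total_exponent: float     # alpha + beta
    prefactor: float          # exp(-alpha*beta/(alpha+beta) |AB|^2)
    degree: int               # lA + lB: the series terminates at this rank


def iter_primitive_pairs(wavefunction):
    """All ordered primitive pairs (both (a,b) and (b,a) are produced;
    each carries exactly its own D_mu,nu block contribution)."""
    basis = ShellBasis(wavefunction.geometry, wavefunction.shells)
    for a, sa in enumerate(basis.shells):
        for b, sb in enumerate(basis.shells):
            AB2 = float(np.sum((sa.center - sb.center) ** 2))
            for ia, al in enumerate(sa.alphas):
                for ib, be in enumerate(sb.alphas):
                    p = al + be
                    P = (al * sa.center + be * sb.center) / p
                    yield PrimitivePairDensity(
                        a, b, float(al), float(be), P * BOHR_ANGSTROM,
                        float(p), float(np.exp(-al * be / p * AB2)),
                        sa.l + sb.l)


def pair_multipoles(pair: PrimitivePairDensity, wavefunction,
                    lmax: int | None = None) -> MultipoleSeries:
    """Exact multipole series of one primitive pair about its overlap center.

    The series terminates at rank lA + lB; ranks above that are
    identically zero.  Components carry the electron charge sign (-1).
    """
    basis = ShellBasis(wavefunction.geometry, wavefunction.shells)
    sa, sb = basis.shells[pair.shell_a], basis.shells[pair.shell_b]
    if lmax is None:
        lmax = pair.degree
    ia = int(np.argmin(np.abs(sa.alphas - pair.alpha)))
    ib = int(np.argmin(np.abs(sb.alphas - pair.beta)))
    dm = np.asarray(wavefunction.density)
    block = dm[sa.ao_start: sa.ao_start + sa.nao,
               sb.ao_start: sb.ao_start + sb.nao]
    comp_polys = _solid.real_poly_table(lmax)[: _solid.n_components(lmax)]
    M = basis._pair_cart_moments(sa, sb, ia, ib,
                                 pair.center / BOHR_ANGSTROM, comp_polys)
    w = sa.wnorm[ia] * sb.wnorm[ib]
    dcart = sa.T.T @ block @ sb.T
    q = -w * np.einsum("mn,mnc->c", dcart, M)
    return MultipoleSeries(pair.center, lmax, q, label="pair")


# ----------------------------------------------------------------------
# decomposition (expensive part, site-independent)
# ----------------------------------------------------------------------

@dataclass
class DensityDecomposition:
    """Site-independent decomposition of a molecular charge density.

    positions/series: overlap-center multipole contributions (electrons);
    grid_points/grid_charges: pointwise diffuse charge (grid path only);
    nuclei: (charges, positions) point contributions.
    """

    lmax: int
    positions: np.ndarray           # (n, 3) Angstrom
    series: np.ndarray              # (n, (lmax+1)^2)
    nuclear_charges: np.ndarray
    nuclear_positions: np.ndarray   # Angstrom
    grid_points: np.ndarray | None = None    # (m, 3) Angstrom
    grid_charges: np.ndarray | None = None   # (m,) e (negative = electrons)
    metadata: dict = field(default_factory=dict)


def _analytic_contributions(wavefunction, lmax, min_exponent=0.0):
    """Overlap-center series for every primitive pair with combined
    exponent >= min_exponent.  Returns (positions Angstrom, series)."""
    basis = ShellBasis(wavefunction.geometry, wavefunction.shells)
    dm = np.asarray(wavefunction.density)
    comp_polys = _solid.real_poly_table(lmax)[: _solid.n_components(lmax)]
    ncomp = _solid.n_components(lmax)
    pos_list, q_list = [], []
    for a, sa in enumerate(basis.shells):
        ra = slice(sa.ao_start, sa.ao_start + sa.nao)
        for b, sb in enumerate(basis.shells):
            rb = slice(sb.ao_start, sb.ao_start + sb.nao)
            dcart = sa.T.T @ dm[ra, rb] @ sb.T
            for ia, al in enumerate(sa.alphas):
                for ib, be in enumerate(sb.alphas):
                    p = al + be
                    if p < min_exponent:
                        continue
                    P = (al * sa.center + be * sb.center) / p
                    M = basis._pair_cart_moments(sa, sb, ia, ib, P, comp_polys)
                    w = sa.wnorm[ia] * sb.wnorm[ib]
                    q = -w * np.einsum("mn,mnc->c", dcart, M)
                    pos_list.append(P * BOHR_ANGSTROM)
                    q_list.append(q)
    if not pos_list:
        return np.zeros((0, 3)), np.zeros((0, ncomp))
    return np.array(pos_list), np.array(q_list)


def _primitive_expansion(basis):
    """Primitive-AO expansion: C2P (nprim_ao x nao) with contracted AO =
    sum_p C2P[p, mu] prim_ao_p, plus per-primitive-AO exponents and shells."""
    rows = []
    exps = []
    shells_of = []
    nao = basis.nao
    for si, sh in enumerate(basis.shells):
        for ip, (a, w) in enumerate(zip(sh.alphas, sh.wnorm)):
            for comp in range(sh.nao):
                row = np.zeros(nao)
                row[sh.ao_start + comp] = w
                rows.append(row)
                exps.append(a)
                shells_of.append((si, comp))
    return np.array(rows), np.array(exps), shells_of


def _diffuse_density_on_grid(wavefunction, basis, pts_bohr, switch):
    """Electron density of all primitive pairs with combined exponent
    below `switch`, evaluated at grid points."""
    C2P, pexp, pmeta = _primitive_expansion(basis)
    dm = np.asarray(wavefunction.density)
    Dp = C2P @ dm @ C2P.T          # primitive-basis density
    mask = (pexp[:, None] + pexp[None, :]) < switch
    Dp = np.where(mask, Dp, 0.0)
    keep = np.any(mask, axis=1)
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        return np.zeros(len(pts_bohr))
    Dp = Dp[np.ix_(idx, idx)]
    # map kept primitive-AO index -> (shell, primitive, component)
    flat = []
    for si, sh in enumerate(basis.shells):
        for ip in range(len(sh.alphas)):
            for comp in range(sh.nao):
                flat.append((si, ip, comp))
    kept = [flat[p] for p in idx]
    from ._gauss import CART_ORDER
    rho = np.zeros(len(pts_bohr))
    chunk = 40000
    for lo in range(0, len(pts_bohr), chunk):
        pts = pts_bohr[lo: lo + chunk]
        vals = np.empty((len(pts), idx.size))
        col = 0
        while col < len(kept):
            si, ip, _ = kept[col]
            sh = basis.shells[si]
            d = pts - sh.center
            r2 = np.einsum("pi,pi->p", d, d)
            rad = np.exp(-sh.alphas[ip] * r2)
            mono = np.ones((len(pts), ncart(sh.l)))
            for m, (i, j, k) in enumerate(CART_ORDER[sh.l]):
                mono[:, m] = d[:, 0] ** i * d[:, 1] ** j * d[:, 2] ** k
            block = rad[:, None] * (mono @ sh.T.T)      # all components
            while col < len(kept) and kept[col][:2] == (si, ip):
                vals[:, col] = block[:, kept[col][2]]
                col += 1
        rho[lo: lo + chunk] = np.einsum("pi,ij,pj->p", vals, Dp, vals,
                                        optimize=True)
    return rho


def decompose(wavefunction, lmax: int,
              exponent_switch: float | None = None,
              grid_spec: dict | None = None) -> DensityDecomposition:
    """Site-independent density decomposition (reused across site sets).

    exponent_switch None: fully analytic.  Otherwise primitive pairs with
    combined exponent below the switch are tabulated as pointwise charges
    on a Becke-weighted molecular grid.
    """
    geo = wavefunction.geometry
    meta = {"lmax": lmax, "exponent_switch": exponent_switch}
    if exponent_switch is None or exponent_switch <= 0.0:
        pos, series = _analytic_contributions(wavefunction, lmax)
        gp = gq = None
    else:
        pos, series = _analytic_contributions(wavefunction, lmax,
                                              min_exponent=exponent_switch)
        from ._grid import molecular_grid
        spec = dict(DEFAULT_GRID_SPEC)
        spec.update(grid_spec or {})
        meta["grid_spec"] = spec
        basis = ShellBasis(geo, wavefunction.shells)
        pts, w = molecular_grid(geo, **spec)
        if len(pts) == 0:
            raise ValueError("empty quadrature grid")
        rho = _diffuse_density_on_grid(wavefunction, basis, pts,
                                       exponent_switch)
        gq = -(w * rho)                       # electron charge, e
        keep = np.abs(gq) > 1e-14             # drop chargeless far points
        gq = gq[keep]
        gp = pts[keep] * BOHR_ANGSTROM
    return DensityDecomposition(
        lmax, pos, series, geo.nuclear_charges, geo.positions,
        grid_points=gp, grid_charges=gq, metadata=meta)


# ----------------------------------------------------------------------
# allocation
# ----------------------------------------------------------------------

def allocate(decomposition: DensityDecomposition, sites: SiteSet,
             grid_partition: str = "smooth"):
    """Assign every analytic contribution to its (radius-scaled) nearest
    site, translate the finite series there and accumulate; divide the
    pointwise grid charge between sites with smooth fuzzy-cell weights
    (`grid_partition='nearest'` switches to hard nearest-site points).
    Returns one MultipoleSeries per site (site order)."""
    dec = decomposition
    lmax = dec.lmax
    ncomp = _solid.n_components(lmax)
    acc = np.zeros((len(sites), ncomp))
    spos = sites.positions

    if len(dec.positions):
        # scaled distances; contributions exactly tied between sites (bond
        # midpoints of symmetry-equivalent pairs) are split equally, which
        # keeps the allocation rotation-invariant on symmetric molecules
        d = np.linalg.norm(dec.positions[:, None, :] - spos[None], axis=2)
        d /= sites.radii[None, :]
        dmin = d.min(axis=1)
        tol = 1e-9 * np.maximum(dmin, 1e-3)
        for i in range(len(dec.positions)):
            owners = np.nonzero(d[i] <= dmin[i] + tol[i])[0]
            share = 1.0 / owners.size
            for s in owners:
                disp = (dec.positions[i] - spos[s]) / BOHR_ANGSTROM
                acc[s] += share * _solid.translation_apply(
                    dec.series[i], lmax, disp)

    if dec.grid_points is not None and len(dec.grid_points):
        if grid_partition == "smooth":
            W = _becke_site_weights(dec.grid_points, sites)
            for s in range(len(sites)):
                w = dec.grid_charges * W[:, s]
                sel = np.abs(w) > 1e-16
                if not np.any(sel):
                    continue
                d = (dec.grid_points[sel] - spos[s]) / BOHR_ANGSTROM
                acc[s] += w[sel] @ _solid.eval_real(d, lmax)
        elif grid_partition == "nearest":
            owners = _assign_many(dec.grid_points, sites)
            for s in range(len(sites)):
                sel = owners == s
                if not np.any(sel):
                    continue
                d = (dec.grid_points[sel] - spos[s]) / BOHR_ANGSTROM
                R = _solid.eval_real(d, lmax)          # (npts, ncomp)
                acc[s] += dec.grid_charges[sel] @ R
        else:
            raise ValueError("grid_partition must be 'smooth' or 'nearest'")

    # nuclear point charges
    nuc_owners = _assign_many(dec.nuclear_positions, sites)
    for z, p, s in zip(dec.nuclear_charges, dec.nuclear_positions, nuc_owners):
        disp = (p - spos[s]) / BOHR_ANGSTROM
        acc[s] += z * _solid.eval_real(disp, lmax)

    out = []
    for s, site in enumerate(sites):
        cap = lmax if site.max_rank is None else min(site.max_rank, lmax)
        series = MultipoleSeries(site.position, lmax, acc[s], site.label)
        if cap < lmax:
            series = MultipoleSeries(
                site.position, cap, acc[s][: _solid.n_components(cap)],
                site.label)
        out.append(series)
    return out


def distribute_analytic(wavefunction, sites: SiteSet, lmax: int):
    """Fully analytic DMA: exact nearest-site allocation of every
    primitive-pair series.  Recombined site series reproduce the direct
    molecular moments at every rank <= lmax."""
    return allocate(decompose(wavefunction, lmax), sites)


def distribute_grid(wavefunction, sites: SiteSet, lmax: int,
                    exponent_switch: float = DEFAULT_EXPONENT_SWITCH,
                    grid_spec: dict | None = None,
                    grid_partition: str = "smooth"):
    """DMA with numerical allocation of diffuse primitive pairs.

    exponent_switch = 0 reduces to the analytic path exactly."""
    if exponent_switch < 0:
        raise ValueError("exponent_switch must be >= 0")
    if exponent_switch == 0.0:
        return distribute_analytic(wavefunction, sites, lmax)
    dec = decompose(wavefunction, lmax, exponent_switch, grid_spec)
    return allocate(dec, sites, grid_partition=grid_partition)
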