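"""Quadrupole-based aromaticity descriptors.

Six descriptors are computed from distributed rank-2 multipoles, all in
e*a0^2 and conventionally normalized by the benzene reference values:

  q2mag_ring    sum over ring-atom sites of |Q2| (per-site, untranslated)
  q2zz_ring     sum over ring-atom sites of Q20
  q2mag_origin  |Q2| of the total series referred to r = (0, 0, 0)
  q2zz_origin   Q20 of the total series referred to r = (0, 0, 0)
  q2mag_probe   |Q2| of the series allocated to the probe site (0, 0, 1 A)
  q2zz_probe    Q20 of that probe-site series

Reading of the "origin" descriptors: the *total* series translated to the
origin (for a neutral molecule with vanishing dipole this is
origin-independent and free of allocation choices).  The alternative
per-atom-translated-magnitude reading is available through
``origin_reading='atom-sum'`` for sensitivity checks.

The molecule must be oriented first: ring centroid at the origin and the
ring-plane normal along +z (`orient_to_ring_plane`), matching the
convention that out-of-plane (pi) density appears in Q20.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dma_engine import (DEFAULT_EXPONENT_SWITCH, SiteSet, allocate,
                         decompose, distribute_analytic)
from .io_formats import Geometry
from .multipole_math import MultipoleSeries, q2_magnitude, sum_series_at, translate_series

__all__ = [
    "DESCRIPTOR_NAMES", "DEFAULT_Z_LIST", "PROBE_HEIGHT",
    "RingSpec", "DescriptorSet", "RigidTransform",
    "orient_to_ring_plane", "compute_descriptors", "normalize_to_reference",
    "descriptors_from_wavefunction", "z_scan",
]

DESCRIPTOR_NAMES = ("q2mag_ring", "q2zz_ring", "q2mag_origin",
                    "q2zz_origin", "q2mag_probe", "q2zz_probe")

#: probe height (Angstrom) above the ring center; near the maximum of the
#: pi density, where the out-of-plane quadrupole is largest
PROBE_HEIGHT = 1.0

#: the z-scan heights (Angstrom): 0, 0.5, a0, then 1..4.5 in 0.5 steps
DEFAULT_Z_LIST = (0.0, 0.5, 0.529, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5)

_POS_TOL = 1e-6


@dataclass
class RingSpec:
    """Ordered ring-atom indices (0-based) and a planarity tolerance."""

    indices: tuple
    planarity_tol: float = 0.05   # Angstrom RMS before a warning flag

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) < 3 or len(set(idx)) != len(idx):
            raise ValueError("a ring needs >= 3 distinct atom indices")
        self.indices = idx

    def validate(self, geometry: Geometry):
        if max(self.indices) >= len(geometry) or min(self.indices) < 0:
            raise IndexError("ring index outside the geometry")


@dataclass
class RigidTransform:
    """r -> rotation @ (r + shift)."""

    rotation: np.ndarray
    shift: np.ndarray

    def apply_points(self, pts):
        return (np.asarray(pts, float) + self.shift) @ self.rotation.T

    def apply_geometry(self, geometry: Geometry) -> Geometry:
        return geometry.transformed(self.rotation, self.shift)

    def apply_wavefunction(self, wfn):
        from ._rotate import rotate_wavefunction
        return rotate_wavefunction(wfn, self.rotation, self.shift)


@dataclass
class DescriptorSet:
    """The six descriptor values, raw and (optionally) normalized."""

    label: str
    raw: dict
    normalized: dict | None = None
    reference: str | None = None
    ring_rms: float = 0.0
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    undefined: tuple = ()

    def __post_init__(self):
        for name in ("q2mag_ring", "q2mag_origin", "q2mag_probe"):
            if name in self.raw and self.raw[name] < 0:
                raise ValueError(f"{name} is a norm and cannot be negative")

    def as_record(self) -> dict:
        rec = {"label": self.label}
        rec.update({k: self.raw.get(k) for k in DESCRIPTOR_NAMES})
        for k in DESCRIPTOR_NAMES:
            rec[f"{k}_norm"] = (self.normalized or {}).get(k)
        rec["reference"] = self.reference
        rec["ring_rms_ang"] = self.ring_rms
        rec["normal_x"], rec["normal_y"], rec["normal_z"] = self.normal
        return rec


# ----------------------------------------------------------------------
# orientation
# ----------------------------------------------------------------------

def ring_plane_diagnostics(geometry: Geometry, ring: RingSpec):
    """(centroid, unit normal, RMS out-of-plane deviation in Angstrom)."""
    ring.validate(geometry)
    pts = geometry.positions[list(ring.indices)]
    centroid = pts.mean(axis=0)
    d = pts - centroid
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    if s[1] < 1e-8:
        raise ValueError("ring atoms are collinear; no plane is defined")
    normal = vt[2]
    # deterministic sign: largest-magnitude component positive
    i = int(np.argmax(np.abs(normal)))
    if normal[i] < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((d @ normal) ** 2)))
    return centroid, normal, rms


def orient_to_ring_plane(geometry: Geometry, ring: RingSpec):
    """Rigid transform placing the ring centroid at the origin and the
    best-fit ring normal along +z (first ring atom fixing the +x
    direction).  Returns (oriented geometry, RigidTransform); applying
    the operation twice is the identity to numerical precision."""
    centroid, normal, _ = ring_plane_diagnostics(geometry, ring)
    z = normal
    # in-plane x axis from the first ring atom
    r0 = geometry.positions[ring.indices[0]] - centroid
    x = r0 - (r0 @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-10:  # ring atom on the axis: fall back to any perpendicular
        x = np.eye(3)[int(np.argmin(np.abs(z)))]
        x = x - (x @ z) * z
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    rot = np.vstack([x, y, z])
    tr = RigidTransform(rotation=rot, shift=-centroid)
    return tr.apply_geometry(geometry), tr


# ----------------------------------------------------------------------
# descriptors
# ----------------------------------------------------------------------

def _find_site(sites: SiteSet, position, what: str) -> int:
    pos = np.asarray(position, float)
    for i, s in enumerate(sites):
        if not s.is_atom and np.linalg.norm(s.position - pos) < _POS_TOL:
            return i
    raise ValueError(
        f"site set lacks the {what} expansion site at {pos}; request it via "
        f"SiteSet.from_geometry(geometry, extra=[('{what}', {tuple(pos)})])")


def compute_descriptors(site_multipoles, sites: SiteSet, ring: RingSpec,
                        reference: "DescriptorSet | None" = None,
                        label: str = "mol", probe_height: float = PROBE_HEIGHT,
                        origin_reading: str = "total",
                        geometry: Geometry | None = None) -> DescriptorSet:
    """Six descriptors from one allocation of site multipoles.

    The sites must include every ring atom and a probe site at
    (0,0,probe_height); every involved series needs rank >= 2.  An
    origin expansion site may be present (its series then simply joins
    the translated total); it is not required, because the origin
    descriptors are read from the partition-independent total.  The
    geometry is assumed oriented (ring plane = xy).
    """
    series = list(site_multipoles)
    if len(series) != len(sites):
        raise ValueError("one multipole series per site expected")
    atom_site_idx = [i for i, s in enumerate(sites) if s.is_atom]
    iprobe = _find_site(sites, (0.0, 0.0, probe_height), "probe")
    for i in set(atom_site_idx) | {iprobe}:
        if series[i].lmax < 2:
            raise ValueError(
                f"site {sites.sites[i].label!r} carries rank {series[i].lmax} < 2")

    ring_sites = [series[atom_site_idx[i]] for i in ring.indices]
    total = sum_series_at((0.0, 0.0, 0.0), series)
    if origin_reading == "total":
        q2mag_origin = q2_magnitude(total)
    elif origin_reading == "atom-sum":
        q2mag_origin = sum(
            q2_magnitude(translate_series(series[i], (0.0, 0.0, 0.0)))
            for i in atom_site_idx)
    else:
        raise ValueError("origin_reading must be 'total' or 'atom-sum'")
    raw = {
        "q2mag_ring": sum(q2_magnitude(s) for s in ring_sites),
        "q2zz_ring": sum(s.component(2, "0") for s in ring_sites),
        "q2mag_origin": q2mag_origin,
        "q2zz_origin": total.component(2, "0"),
        "q2mag_probe": q2_magnitude(series[iprobe]),
        "q2zz_probe": series[iprobe].component(2, "0"),
    }
    rms, normal = 0.0, np.array([0.0, 0.0, 1.0])
    if geometry is not None:
        _, normal, rms = ring_plane_diagnostics(geometry, ring)
    ds = DescriptorSet(label, raw, ring_rms=rms, normal=normal)
    if reference is not None:
        ds = normalize_to_reference(ds, reference)
    return ds


def normalize_to_reference(raw: DescriptorSet,
                           reference: DescriptorSet) -> DescriptorSet:
    """Elementwise signed division by the reference raw values.

    A zero reference component flags that entry as undefined (NaN) rather
    than dropping it."""
    normalized = {}
    undefined = []
    for k in DESCRIPTOR_NAMES:
        ref = reference.raw[k]
        if ref == 0.0:
            normalized[k] = float("nan")
            undefined.append(k)
        else:
            normalized[k] = raw.raw[k] / ref
    return DescriptorSet(raw.label, dict(raw.raw), normalized,
                         reference.label, raw.ring_rms, raw.normal,
                         tuple(undefined))


# ----------------------------------------------------------------------
# pipeline: wavefunction -> descriptors / z-scan
# ----------------------------------------------------------------------

def _engine_sites(geometry, extra, radii_table=None, default_radius=1.0):
    return SiteSet.from_geometry(geometry, extra=extra,
                                 default_radius=default_radius,
                                 radii_table=radii_table)


def descriptors_from_wavefunction(
        wfn, ring: RingSpec, reference: "DescriptorSet | None" = None,
        label: str = "mol", lmax: int = 2, grid: bool = True,
        exponent_switch: float = DEFAULT_EXPONENT_SWITCH,
        grid_spec: dict | None = None, orient: bool = True,
        probe_height: float = PROBE_HEIGHT,
        origin_reading: str = "total") -> DescriptorSet:
    """Full pipeline: orient, distribute, and reduce to the six descriptors.

    The expansion sites are the atoms plus the single probe at
    (0, 0, probe_height).  No empty site is placed at the ring center:
    on symmetric rings the center is exactly equidistant from center and
    carbon for whole families of overlap centers, and letting an empty
    site compete there makes the ring-atom descriptors discontinuous
    functions of the geometry.  The origin descriptors instead use the
    translated total, which is independent of the partition altogether.
    """
    ring.validate(wfn.geometry)
    if orient:
        _, tr = orient_to_ring_plane(wfn.geometry, ring)
        wfn = tr.apply_wavefunction(wfn)
    _, normal, rms = ring_plane_diagnostics(wfn.geometry, ring)
    geo = wfn.geometry
    dec = decompose(wfn, lmax, exponent_switch if grid else None, grid_spec)
    sites_p = _engine_sites(geo, [("probe", (0.0, 0.0, probe_height))])
    out_p = allocate(dec, sites_p)

    ring_sites = [out_p[i] for i in ring.indices]   # atoms come first
    total = sum_series_at((0.0, 0.0, 0.0), out_p)
    if origin_reading == "total":
        q2mag_origin = q2_magnitude(total)
    else:
        q2mag_origin = sum(
            q2_magnitude(translate_series(out_p[i], (0.0, 0.0, 0.0)))
            for i in range(len(geo)))
    probe = out_p[-1]
    raw = {
        "q2mag_ring": sum(q2_magnitude(s) for s in ring_sites),
        "q2zz_ring": sum(s.component(2, "0") for s in ring_sites),
        "q2mag_origin": q2mag_origin,
        "q2zz_origin": total.component(2, "0"),
        "q2mag_probe": q2_magnitude(probe),
        "q2zz_probe": probe.component(2, "0"),
    }
    ds = DescriptorSet(label, raw, ring_rms=rms, normal=normal)
    if reference is not None:
        ds = normalize_to_reference(ds, reference)
    return ds


def z_scan(wfn, ring: RingSpec, z_values=DEFAULT_Z_LIST, lmax: int = 2,
           grid: bool = True, exponent_switch: float = DEFAULT_EXPONENT_SWITCH,
           grid_spec: dict | None = None, orient: bool = True):
    """Probe-site Q20 at (0, 0, z) for each z (Angstrom).

    One engine decomposition is reused; each z runs its own allocation
    with sites = atoms + that single probe.  Returns [(z, Q20), ...] in
    input order."""
    z_values = [float(z) for z in z_values]
    if not all(np.isfinite(z_values)):
        raise ValueError("z values must be finite")
    ring.validate(wfn.geometry)
    if orient:
        _, tr = orient_to_ring_plane(wfn.geometry, ring)
        wfn = tr.apply_wavefunction(wfn)
    geo = wfn.geometry
    dec = decompose(wfn, lmax, exponent_switch if grid else None, grid_spec)
    out = []
    atom_pos = geo.positions
    for z in z_values:
        probe = np.array([0.0, 0.0, z])
        if np.min(np.linalg.norm(atom_pos - probe, axis=1)) < _POS_TOL:
            raise ValueError(f"probe at z={z} coincides with an atom")
        sites = _engine_sites(geo, [("probe", tuple(probe))])
        alloc = allocate(dec, sites)
        out.append((z, alloc[-1].component(2, "0")))
    return out
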