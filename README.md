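# qdma

Distributed multipole analysis (DMA) of Gaussian-basis electron
densities, and a set of six aromaticity descriptors built from the
distributed quadrupole tensor **Q**₂.

## The problem

Aromaticity — the enhanced stability of cyclic π-delocalized systems —
is not an observable, so it is quantified through descriptors.  The
quadrupole moment is the first electric multipole that carries
information about electron density *out of the molecular plane*, which
is exactly where aromatic π density lives.  Stone's DMA partitions a
molecular charge density, expressed in a Gaussian basis, into multipole
series **Q**₀, **Q**₁, **Q**₂, … attached to atoms and to any extra
expansion points: each product of two primitive Gaussians is an exact,
*finite* multipole series about its overlap center
P = (αA + βB)/(α + β), which is moved to the nearest expansion site.
Recombining all site series about any origin reproduces the exact
molecular moments.

This package is aimed at quantum chemists who have a one-electron
density matrix (a Gaussian formatted-checkpoint `.fchk` document, at
SCF, MP2 or CC level) or a punch file of precomputed site multipoles,
and want distributed quadrupoles and ring-resolved aromaticity numbers.

## The descriptors

With the ring oriented in the *xy* plane (ring centroid at the origin,
normal along +z), the traceless quadrupole

Θ_zz = Σₐ eₐ rₐ² (3cos²θₐ − 1)/2 = Q₂₀

is negative for oblate (disc-like, π-delocalized) charge distributions.
In real spherical components (Racah normalization, units e·a₀²):
Q₂₀ = Θ_zz, Q₂₁c = (2/√3)Θ_xz, Q₂₁s = (2/√3)Θ_yz,
Q₂₂c = (1/√3)(Θ_xx − Θ_yy), Q₂₂s = (2/√3)Θ_xy, and the rotation
invariant |**Q**₂| = (Q₂₀² + Q₂₁c² + Q₂₁s² + Q₂₂c² + Q₂₂s²)^½.

Six descriptors are computed, raw and normalized by the benzene
reference values:

| descriptor      | definition                                              |
|-----------------|---------------------------------------------------------|
| `q2mag_ring`    | Σ over ring-atom sites of \|**Q**₂\|                    |
| `q2zz_ring`     | Σ over ring-atom sites of Q₂₀                            |
| `q2mag_origin`  | \|**Q**₂\| of the total series referred to (0, 0, 0)     |
| `q2zz_origin`   | Q₂₀ of the total series referred to (0, 0, 0)            |
| `q2mag_probe`   | \|**Q**₂\| allocated to a probe site at (0, 0, 1 Å)      |
| `q2zz_probe`    | Q₂₀ allocated to that probe site                         |

The probe height of 1 Å sits at the maximum of the probe-site Q₂₀
profile above the benzene ring (see the z-scan below), near the maximum
of the π density.

## Worked example

```python
from qdma.benchmark_fixtures import build_benzene, density_provider
from qdma.aromaticity import RingSpec, descriptors_from_wavefunction

wfn = density_provider(build_benzene(), "sto-3g", "SCF", label="benzene")
ring = RingSpec((0, 1, 2, 3, 4, 5))
ds = descriptors_from_wavefunction(wfn, ring, grid=False, label="benzene")
for name, value in ds.raw.items():
    print(f"{name:>14}: {value:+.4f} e a0^2")
```

prints

```
    q2mag_ring: +2.9876 e a0^2
     q2zz_ring: +2.5442 e a0^2
  q2mag_origin: +2.8967 e a0^2
   q2zz_origin: -2.8967 e a0^2
   q2mag_probe: +0.2072 e a0^2
    q2zz_probe: +0.2072 e a0^2
```

`q2zz_origin` is negative: benzene's charge distribution is oblate, the
π cloud spread above and below the ring plane.  Normalizing a distorted
ring against this benzene reference (`normalize_to_reference`) gives the
six dimensionless aromaticity indices; deviations from 1 grow with the
distortion.

The same pipeline is available from the shell:

```sh
qdma distribute molecule.fchk --density MP2 --extra-site 0,0,1.0 -o sites.punch
qdma arom molecule.fchk --ring 1,2,3,4,5,6 --density MP2 -o table.csv
qdma zscan molecule.fchk --ring 1,2,3,4,5,6
qdma fixtures benzene --t1 0.1 -o distorted.xyz
```

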