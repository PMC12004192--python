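"""Geometry builders, distortions, classical fixtures, trend harness."""
import numpy as np
import pytest

from qdma.aromaticity import DESCRIPTOR_NAMES, DescriptorSet, \
    normalize_to_reference, ring_plane_diagnostics, RingSpec
from qdma.benchmark_fixtures import (DistortionSpec, build_benzene, build_co2,
                                     build_linear, classical_fixture,
                                     density_provider, distort, trend_report)
from qdma.multipole_math import (BOHR_ANGSTROM, MultipoleSeries,
                                 q2_magnitude, sum_series_at)


def _ring_bonds(geo):
    p = geo.positions[:6]
    return np.array([np.linalg.norm(p[(k + 1) % 6] - p[k]) for k in range(6)])


class TestBenzeneBuilder:
    def test_six_equal_cc_bonds(self):
        bonds = _ring_bonds(build_benzene())
        assert np.allclose(bonds, 1.39, atol=1e-12)

    def test_centroid_and_planarity(self):
        geo = build_benzene()
        assert np.allclose(geo.positions[:6].mean(axis=0), 0.0, atol=1e-12)
        assert np.all(geo.positions[:, 2] == 0.0)

    def test_zero_alternation(self):
        bonds = _ring_bonds(build_benzene())
        assert bonds.max() - bonds.min() == 0.0

    def test_atom_ordering_and_ch_bonds(self):
        geo = build_benzene()
        assert geo.symbols == ["C"] * 6 + ["H"] * 6
        for k in range(6):
            assert np.linalg.norm(
                geo.positions[6 + k] - geo.positions[k]) == pytest.approx(1.09)

    def test_deterministic(self):
        assert np.array_equal(build_benzene().positions,
                              build_benzene().positions)


class TestDistortions:
    def test_t1_zero_is_identity(self):
        base = build_benzene()
        out = distort(DistortionSpec("T1", 0.0), base)
        assert np.array_equal(out.positions, base.positions)

    def test_t1_alternating_bonds(self):
        out = distort(DistortionSpec("T1", 0.1))
        bonds = _ring_bonds(out)
        assert np.allclose(np.sort(bonds)[:3], 1.34, atol=1e-10)
        assert np.allclose(np.sort(bonds)[3:], 1.44, atol=1e-10)
        assert np.all(out.positions[:, 2] == 0.0)  # planar
        assert np.allclose(out.positions[:6].mean(axis=0), 0.0, atol=1e-12)

    def test_t1_ch_length_preserved(self):
        out = distort(DistortionSpec("T1", 0.2))
        for k in range(6):
            assert np.linalg.norm(out.positions[6 + k] - out.positions[k]) \
                == pytest.approx(1.09, abs=1e-10)

    def test_t2_in_plane_ch_rock(self):
        out = distort(DistortionSpec("T2", 10.0))
        base = build_benzene()
        assert np.allclose(out.positions[:6], base.positions[:6])
        assert np.all(out.positions[:, 2] == 0.0)
        ch_b = base.positions[6] - base.positions[0]
        ch_o = out.positions[6] - out.positions[0]
        cos = ch_b @ ch_o / np.linalg.norm(ch_b) / np.linalg.norm(ch_o)
        assert np.degrees(np.arccos(cos)) == pytest.approx(10.0, abs=1e-8)

    def test_t4_chair_breaks_planarity(self):
        flat = distort(DistortionSpec("T4", 0.0))
        bent = distort(DistortionSpec("T4", 10.0))
        ring = RingSpec(tuple(range(6)))
        assert ring_plane_diagnostics(flat, ring)[2] == pytest.approx(0.0)
        assert ring_plane_diagnostics(bent, ring)[2] > 0.05
        z = bent.positions[:6, 2]
        assert np.all(z[::2] > 0) and np.all(z[1::2] < 0)

    def test_t3_boat_lifts_para_pair(self):
        bent = distort(DistortionSpec("T3", 10.0))
        z = bent.positions[:6, 2]
        assert z[0] > 0 and z[3] > 0
        assert np.allclose(z[[1, 2, 4, 5]], 0.0)

    def test_t5_ch_wag_keeps_carbons(self):
        bent = distort(DistortionSpec("T5", 15.0))
        base = build_benzene()
        assert np.allclose(bent.positions[:6], base.positions[:6])
        assert np.abs(bent.positions[6:, 2]).min() > 0.1

    def test_parameter_range_enforced(self):
        with pytest.raises(ValueError):
            DistortionSpec("T1", 0.5)
        with pytest.raises(ValueError):
            DistortionSpec("T9", 1.0)


class TestLinearBuilder:
    def test_co2_collinear_and_symmetric(self):
        geo = build_co2()
        p = geo.positions
        assert np.allclose(p[:, :2], 0.0)
        assert p[0, 2] == pytest.approx(-p[2, 2])
        assert p[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_center_of_mass_at_origin(self):
        geo = build_linear(["C", "O"], [1.128])
        m = np.array([12.011, 15.999])
        com = m @ geo.positions / m.sum()
        assert np.allclose(com, 0.0, atol=1e-12)

    def test_axial_symmetry_of_moments(self):
        # any axial charge set on this geometry has no off-axis rank-2 terms
        geo = build_co2()
        sites = []
        for q, a in zip([-0.3, 0.6, -0.3], geo.atoms):
            s = MultipoleSeries(a.position, 2)
            s.q[0] = q
            sites.append(s)
        tot = sum_series_at((0, 0, 0), sites)
        assert np.allclose([tot.component(2, k) for k in
                            ("1c", "1s", "2c", "2s")], 0.0, atol=1e-14)


class TestClassicalFixtures:
    @staticmethod
    def _moments(charges, lmax=4):
        sites = []
        for q, p in charges:
            s = MultipoleSeries(p, lmax)
            s.q[0] = q
            sites.append(s)
        return sum_series_at((0, 0, 0), sites)

    def test_axial_quadrupole_closed_form(self):
        tot = self._moments(classical_fixture("axial-quadrupole"))
        assert tot.q[0] == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(tot.rank(1), 0.0, atol=1e-14)
        assert tot.component(2, "0") == pytest.approx(2.0, abs=1e-10)

    def test_square_quadrupole_q22c_only(self):
        tot = self._moments(classical_fixture("square-quadrupole"))
        r2 = tot.rank(2)
        assert abs(r2[3]) > 1.0
        assert np.allclose(np.delete(r2, 3), 0.0, atol=1e-12)

    def test_single_charge_translate_oracle(self):
        (q, p), = classical_fixture("single-charge")
        tot = self._moments([(q, p)])
        from qdma.multipole_math import real_regular_harmonics
        tab = real_regular_harmonics(np.asarray(p) / BOHR_ANGSTROM, 4)
        for i, lk in enumerate(
                [(l, k) for l in range(5)
                 for k in (["0"] + sum(([f"{m}c", f"{m}s"]
                                        for m in range(1, l + 1)), []))]):
            assert tot.q[i] == pytest.approx(q * tab[lk], abs=1e-12)

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown"):
            classical_fixture("octopole-farm")


class TestDensityProvider:
    def test_cache_hit_without_backend(self):
        wfn = density_provider(build_benzene(), "sto-3g", "SCF",
                               label="benzene", allow_compute=False)
        assert wfn.nao == 36

    def test_benzene_electron_count(self):
        wfn = density_provider(build_benzene(), "sto-3g", "SCF",
                               label="benzene", allow_compute=False)
        assert wfn.electron_count() == pytest.approx(42.0, abs=1e-6)

    def test_missing_fixture_actionable_error(self):
        geo = build_linear(["O", "O"], [1.21])
        with pytest.raises(FileNotFoundError, match="cached density"):
            density_provider(geo, "sto-3g", "SCF", label="o2",
                             allow_compute=False)

    def test_cache_determinism(self, tmp_path):
        geo = build_linear(["H", "H"], [0.74])
        a = density_provider(geo, "sto-3g", "SCF", label="h2",
                             cache_dir=str(tmp_path))
        b = density_provider(geo, "sto-3g", "SCF", label="h2",
                             cache_dir=str(tmp_path))
        files = list(tmp_path.glob("*.fchk"))
        assert len(files) == 1
        assert np.allclose(a.density, b.density, atol=1e-12)


class TestTrendReport:
    @staticmethod
    def _series(values):
        ref_raw = {k: 1.0 for k in DESCRIPTOR_NAMES}
        ref = DescriptorSet("ref", ref_raw)
        out = []
        for i, v in enumerate(values):
            ds = DescriptorSet(f"p{i}", {k: abs(v) if k.startswith("q2mag")
                                         else v for k in DESCRIPTOR_NAMES})
            out.append((float(i), normalize_to_reference(ds, ref)))
        return out

    def test_monotone_is_concordant(self):
        rep = trend_report(self._series([1.0, 0.9, 0.8, 0.7]), "decreasing")
        assert set(rep.values()) == {"concordant"}

    def test_tiny_single_inversion_is_minor(self):
        rep = trend_report(self._series([1.0, 0.9, 0.90001, 0.7]),
                           "decreasing", minor_threshold=1e-3)
        assert set(rep.values()) == {"minor-deviation"}

    def test_reversed_is_discordant(self):
        rep = trend_report(self._series([0.7, 0.8, 0.9, 1.0]), "decreasing")
        assert set(rep.values()) == {"discordant"}

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            trend_report(self._series([1.0]), "decreasing")
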