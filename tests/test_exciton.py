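"""Coupled-oscillator exciton model: couplings, eigenstates, spectra."""

import numpy as np
import pytest

from specpair.chem import build_ideal_chlorin
from specpair.exciton import (
    ChromophoreSite,
    ExcitonState,
    ExcitonSystem,
    SpectrumParams,
    coupling_from_band_positions,
    diagonalize,
    exciton_dipoles,
    point_dipole_coupling,
    qy_sites_from_chlorins,
    simulate_spectra,
    wavelength_to_wavenumber,
)
from specpair.geometry import RigidTransform, rotation_about_axis


def _site(center, direction, mu=5.0, e0=14970.0):
    return ChromophoreSite(np.array(center, float), e0, mu, np.array(direction, float))


class TestConversions:
    def test_wavelength_to_wavenumber(self):
        assert wavelength_to_wavenumber(668.0) == pytest.approx(14970.06, abs=0.01)
        assert wavelength_to_wavenumber(1000.0) == pytest.approx(10000.0)

    def test_round_trip(self):
        lam = 673.5
        assert 1e7 / wavelength_to_wavenumber(lam) == pytest.approx(lam, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            wavelength_to_wavenumber(0.0)

    def test_band_splitting_and_coupling(self):
        splitting, coupling = coupling_from_band_positions(668.0, 690.0)
        assert round(splitting) == 477
        assert round(coupling) == 239

    def test_equal_bands_give_zero(self):
        assert coupling_from_band_positions(670.0, 670.0) == (0.0, 0.0)

    def test_wider_separation(self):
        splitting, coupling = coupling_from_band_positions(650.0, 700.0)
        assert splitting == pytest.approx(1098.9, abs=0.1)
        assert coupling == pytest.approx(549.5, abs=0.1)


class TestPointDipoleCoupling:
    def test_side_by_side_parallel(self):
        # kappa = 1; mu1 mu2 / R^3 = 25 -> V = 5.04 * 25 = 126 cm^-1
        v = point_dipole_coupling(_site([0, 0, 0], [0, 1, 0]), _site([10, 0, 0], [0, 1, 0]))
        assert v == pytest.approx(126.0, abs=0.1)

    def test_head_to_tail_collinear(self):
        v = point_dipole_coupling(_site([0, 0, 0], [1, 0, 0]), _site([10, 0, 0], [1, 0, 0]))
        assert v == pytest.approx(-252.0, abs=0.1)

    def test_orthogonal_arrangement_zero(self):
        v = point_dipole_coupling(_site([0, 0, 0], [0, 1, 0]), _site([10, 0, 0], [0, 0, 1]))
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_flip_one_dipole_negates_coupling(self, rng):
        for _ in range(10):
            d1, d2 = rng.normal(size=(2, 3))
            s1 = _site(rng.normal(size=3), d1)
            s2 = _site(rng.normal(size=3) + 8.0, d2)
            s2_flipped = _site(s2.center, -d2)
            assert point_dipole_coupling(s1, s2_flipped) == pytest.approx(
                -point_dipole_coupling(s1, s2), rel=1e-12
            )

    def test_screening_scales_linearly(self):
        s1, s2 = _site([0, 0, 0], [0, 1, 0]), _site([10, 0, 0], [0, 1, 0])
        assert point_dipole_coupling(s1, s2, screening=0.7) == pytest.approx(
            0.7 * point_dipole_coupling(s1, s2)
        )

    def test_coincident_centers_rejected(self):
        with pytest.raises(ValueError):
            point_dipole_coupling(_site([0, 0, 0], [0, 1, 0]), _site([0, 0, 0], [0, 1, 0]))


class TestDiagonalize:
    def test_degenerate_dimer_closed_form(self):
        sites = [_site([0, 0, 0], [0, 1, 0], e0=14970.0), _site([7, 0, 0], [0, 1, 0], e0=14970.0)]
        system = ExcitonSystem(sites, np.array([[0.0, 239.0], [239.0, 0.0]]))
        states = diagonalize(system)
        assert states[0].energy == pytest.approx(14731.0)
        assert states[1].energy == pytest.approx(15209.0)
        for st in states:
            assert np.abs(st.coefficients) == pytest.approx([1, 1] / np.sqrt(2))

    def test_zero_coupling_localized(self):
        sites = [_site([0, 0, 0], [0, 1, 0], e0=14000.0), _site([7, 0, 0], [0, 1, 0], e0=15000.0)]
        system = ExcitonSystem(sites, np.zeros((2, 2)))
        states = diagonalize(system)
        assert [s.energy for s in states] == pytest.approx([14000.0, 15000.0])
        assert abs(states[0].coefficients[0]) == pytest.approx(1.0)

    def test_trace_conservation(self, rng):
        n = 4
        sites = [_site(rng.normal(size=3) * 10, rng.normal(size=3), e0=float(rng.uniform(14000, 16000))) for _ in range(n)]
        V = rng.normal(size=(n, n)) * 50
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        system = ExcitonSystem(sites, V)
        states = diagonalize(system)
        assert sum(s.energy for s in states) == pytest.approx(
            sum(s.site_energy for s in sites), abs=1e-6
        )

    def test_closed_form_matches_eigensolver_on_random_dimers(self, rng):
        for _ in range(20):
            e = float(rng.uniform(14000, 16000))
            v = float(rng.uniform(-500, 500))
            sites = [_site([0, 0, 0], [0, 1, 0], e0=e), _site([7, 0, 0], [0, 1, 0], e0=e)]
            system = ExcitonSystem(sites, np.array([[0.0, v], [v, 0.0]]))
            states = diagonalize(system)
            assert states[0].energy == pytest.approx(e - abs(v), abs=1e-9)
            assert states[1].energy == pytest.approx(e + abs(v), abs=1e-9)


class TestDipolesAndRotatoryStrengths:
    def _chiral_dimer(self, angle=0.5):
        s1 = _site([0, 0, 0], [0, 1, 0], mu=4.6)
        s2 = _site([7, 0, 0], [0, np.cos(angle), np.sin(angle)], mu=4.6)
        return ExcitonSystem.from_sites([s1, s2])

    def test_dipole_strength_conservation(self):
        system = self._chiral_dimer()
        states = exciton_dipoles(system, diagonalize(system))
        total = sum(s.dipole_strength for s in states)
        assert total == pytest.approx(2 * 4.6**2, abs=1e-9)

    def test_conservative_couplet(self):
        system = self._chiral_dimer()
        states = exciton_dipoles(system, diagonalize(system))
        r = [s.rotatory_strength for s in states]
        assert r[0] == pytest.approx(-r[1], abs=1e-9)
        assert abs(r[0]) > 0

    def test_coplanar_parallel_dipoles_no_rotation(self):
        s1 = _site([0, 0, 0], [0, 1, 0])
        s2 = _site([7, 0, 0], [0, 1, 0])
        system = ExcitonSystem.from_sites([s1, s2])
        states = exciton_dipoles(system, diagonalize(system))
        for st in states:
            assert st.rotatory_strength == pytest.approx(0.0, abs=1e-9)

    def test_parallel_side_by_side_strength_distribution(self):
        """In-phase state carries 2 mu^2; out-of-phase carries nothing."""
        s1 = _site([0, 0, 0], [0, 1, 0], mu=5.0)
        s2 = _site([10, 0, 0], [0, 1, 0], mu=5.0)
        system = ExcitonSystem.from_sites([s1, s2])
        states = exciton_dipoles(system, diagonalize(system))
        strengths = sorted(s.dipole_strength for s in states)
        assert strengths[0] == pytest.approx(0.0, abs=1e-9)
        assert strengths[1] == pytest.approx(50.0, abs=1e-9)


class TestSpectra:
    def test_single_state_fwhm(self):
        params = SpectrumParams(grid=np.linspace(12000, 18000, 6001))
        states = [ExcitonState(17000.0, np.array([1.0]), np.zeros(3), 1.0, 0.0)]
        ab, _ = simulate_spectra(states, params)
        half = ab.max() / 2
        above = params.grid[ab >= half]
        assert above.max() - above.min() == pytest.approx(350.0, abs=2.0)

    def test_global_shift_applied(self):
        params = SpectrumParams(grid=np.linspace(10000, 18000, 8001))
        states = [ExcitonState(16000.0, np.array([1.0]), np.zeros(3), 1.0, 0.0)]
        ab, _ = simulate_spectra(states, params)
        peak = params.grid[np.argmax(ab)]
        assert peak == pytest.approx(16000.0 - 0.25 * 8065.54, abs=2.0)

    def test_c2_dimer_cd_integrates_to_zero(self):
        s1 = _site([0, 0, 0], [0, 1, 0], mu=4.6)
        s2 = _site([7, 0, 0], [0, np.cos(0.6), np.sin(0.6)], mu=4.6)
        system = ExcitonSystem.from_sites([s1, s2])
        states = exciton_dipoles(system, diagonalize(system))
        params = SpectrumParams()
        _, cd = simulate_spectra(states, params)
        integral = np.trapezoid(cd, params.grid)
        l1 = np.trapezoid(np.abs(cd), params.grid)
        assert abs(integral) < 1e-6 * l1

    def test_absorbance_linear_in_dipole_strength(self):
        params = SpectrumParams()
        one = [ExcitonState(15000.0, np.array([1.0]), np.zeros(3), 1.0, 0.0)]
        two = [ExcitonState(15000.0, np.array([1.0]), np.zeros(3), 2.0, 0.0)]
        a1, _ = simulate_spectra(one, params)
        a2, _ = simulate_spectra(two, params)
        assert np.trapezoid(a2, params.grid) == pytest.approx(
            2 * np.trapezoid(a1, params.grid)
        )

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            SpectrumParams(grid=np.array([1.0, 3.0, 2.0]))


class TestSitesFromChlorins:
    def test_c2_pair_symmetric(self):
        t1 = build_ideal_chlorin("Zn")
        c2 = RigidTransform(np.diag([-1.0, -1.0, 1.0]), np.array([8.0, 0.0, 0.0]))
        t2 = t1.transformed(c2)
        system = qy_sites_from_chlorins((t1, t2))
        assert system.sites[0].site_energy == system.sites[1].site_energy
        assert abs(system.coupling_matrix[0, 1]) == abs(system.coupling_matrix[1, 0])

    def test_stacked_antiparallel_kappa(self):
        """Antiparallel coplanar-stacked dipoles at 0.7 nm: kappa = -1."""
        t1 = build_ideal_chlorin("Zn")
        flip = RigidTransform(
            rotation_about_axis([0, 0, 1], 180.0), np.array([0.0, 0.0, 7.0])
        )
        t2 = t1.transformed(flip)
        system = qy_sites_from_chlorins((t1, t2), mu=4.6)
        expected = 5.04 * (-1.0) * 4.6**2 / 0.7**3
        assert system.coupling_matrix[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_far_separation_negligible_coupling(self):
        t1 = build_ideal_chlorin("Zn")
        t2 = t1.transformed(RigidTransform(np.eye(3), np.array([60.0, 0, 0])))
        system = qy_sites_from_chlorins((t1, t2))
        assert abs(system.coupling_matrix[0, 1]) < 1.0

    def test_coincident_centers_rejected(self):
        t1 = build_ideal_chlorin("Zn")
        with pytest.raises(ValueError):
            qy_sites_from_chlorins((t1, t1))
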