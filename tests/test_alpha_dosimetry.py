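"""Emission spectra, range-energy interpolation and S-value kernels.

The cross-dose kernel is validated against an independent Monte Carlo
oracle that samples source positions and emission directions at random and
transports each alpha by explicit Euler stepping of the stopping power
(the derivative of the range-energy curve), rather than the closed-form
chord residual-energy difference used by the implementation.
"""

import numpy as np
import pytest

from spheradose.alpha_dosimetry import (EmissionSpectrum, RangeEnergyTable,
                                        load_decay_chain,
                                        load_range_energy_table,
                                        daughter_correction_factor,
                                        point_source_nucleus_dose,
                                        self_svalue, cross_svalue)
from spheradose.geometry import SpheroidConfig
from spheradose.units import MEV_TO_J, sphere_mass_kg


class TestDecayChain:
    def test_parent_only_single_alpha_group(self):
        spec = load_decay_chain("Ac-225", include_daughters=False)
        assert spec.total_yield == pytest.approx(1.0, abs=0.02)
        assert not spec.includes_daughters

    def test_equilibrium_chain_four_alpha_groups(self):
        spec = load_decay_chain("Ac-225", include_daughters=True)
        assert spec.total_yield == pytest.approx(4.0, abs=0.05)

    def test_chain_energy_exceeds_four_parents(self):
        full = load_decay_chain("Ac-225", True)
        parent = load_decay_chain("Ac-225", False)
        assert full.total_energy_mev / parent.total_energy_mev > 4.0

    def test_unknown_chain_rejected(self):
        with pytest.raises(ValueError):
            load_decay_chain("Ra-223")

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            EmissionSpectrum(lines=())


class TestRangeEnergy:
    def test_zero_energy_zero_range(self):
        t = load_range_energy_table()
        assert t.range(0.0) == 0.0

    def test_strictly_increasing(self):
        t = load_range_energy_table()
        e = np.linspace(0.0, t.max_energy_mev, 100)
        assert np.all(np.diff(t.range(e)) > 0)

    def test_round_trip_inverse(self):
        t = load_range_energy_table()
        e = np.linspace(0.05, t.max_energy_mev - 0.05, 200)
        assert np.max(np.abs(t.energy(t.range(e)) - e)) < 1e-6

    def test_out_of_domain_rejected(self):
        t = load_range_energy_table()
        with pytest.raises(ValueError):
            t.range(11.0)
        with pytest.raises(ValueError):
            t.energy(1e4)

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError):
            RangeEnergyTable(np.array([0.0, 1.0, 0.5]),
                             np.array([0.0, 5.0, 6.0]))


class TestSelfSValue:
    def test_full_absorption_limit(self, study_geo):
        # alpha whose range is far below the nucleus radius deposits its full
        # energy: S = E / m_nucleus (1.42 Gy for 1 MeV in a 3-um nucleus)
        table = RangeEnergyTable(np.array([0.0, 1.0, 2.0]),
                                 np.array([0.0, 0.05, 0.10]))
        spec = EmissionSpectrum(lines=((1.0, 1.0),))
        s = self_svalue("nucleus", study_geo, spec, table)
        expected = 1.0 * MEV_TO_J / sphere_mass_kg(3.0)
        assert expected == pytest.approx(1.4165, rel=1e-3)
        assert s == pytest.approx(expected, rel=0.01)

    def test_compartment_ordering(self, study_geo):
        parent = load_decay_chain("Ac-225", include_daughters=False)
        s_n = self_svalue("nucleus", study_geo, parent)
        s_c = self_svalue("cytoplasm", study_geo, parent)
        s_s = self_svalue("cell_surface", study_geo, parent)
        assert s_n >= s_c >= s_s > 0

    def test_unknown_compartment_rejected(self, study_geo):
        with pytest.raises(ValueError):
            self_svalue("membrane", study_geo, load_decay_chain("Ac-225", False))

    def test_daughter_factor_below_energy_ratio(self, study_geo):
        # longer-ranged daughter alphas deposit smaller in-cell fractions, so
        # the self-dose ratio must stay below the chain/parent energy ratio
        full = load_decay_chain("Ac-225", True)
        parent = load_decay_chain("Ac-225", False)
        factor = daughter_correction_factor(study_geo)
        assert 1.0 < factor < full.total_energy_mev / parent.total_energy_mev


class TestEnergyConservation:
    def test_total_deposition_matches_spectrum_energy(self):
        # an absorbing sphere larger than any alpha range must collect the
        # full emitted energy, from any interior source position
        table = load_range_energy_table()
        spec = load_decay_chain("Ac-225", True)
        big = 150.0
        for d in (0.0, 30.0, 60.0):
            dose = point_source_nucleus_dose(d, spec, big, table)
            deposited = dose * sphere_mass_kg(big) / MEV_TO_J
            assert deposited == pytest.approx(spec.total_energy_mev, rel=0.01)


def _mc_cross_svalue(distance, geometry, spectrum, table, n_samples, seed,
                     step=0.05):
    """Monte Carlo oracle: random surface-source positions, cone-importance
    direction sampling, Euler transport of the stopping power."""
    rng = np.random.default_rng(seed)
    rn = geometry.nucleus_radius
    # stopping power from the numerical derivative of the range-energy curve
    e_dense = np.linspace(0.0, table.max_energy_mev, 3000)[1:]
    r_dense = table.range(e_dense)
    dedx = np.gradient(e_dense, r_dense)

    # random source points on the source cell's surface
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    src = np.array([0.0, 0.0, distance]) + geometry.cell_radius * v
    dp = np.linalg.norm(src, axis=1)
    mu0 = np.sqrt(1.0 - (rn / dp) ** 2)
    weight = (1.0 - mu0) / 2.0  # cone solid-angle fraction toward the nucleus

    # orthonormal frame with axis toward the nucleus center
    axis = -src / dp[:, None]
    helper = np.zeros_like(axis)
    helper[:, 0] = 1.0
    swap = np.abs(axis[:, 0]) > 0.9
    helper[swap] = [0.0, 1.0, 0.0]
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axis, e1)
    mu = mu0 + (1.0 - mu0) * rng.random(n_samples)
    phi = 2.0 * np.pi * rng.random(n_samples)
    sin = np.sqrt(1.0 - mu**2)
    u = (mu[:, None] * axis + sin[:, None] * np.cos(phi)[:, None] * e1
         + sin[:, None] * np.sin(phi)[:, None] * e2)

    total = 0.0
    t_max = float(np.max(dp) + rn)
    n_steps = int(np.ceil(t_max / step))
    for energy, yld in spectrum.lines:
        e_cur = np.full(n_samples, energy)
        dep = np.zeros(n_samples)
        for i in range(n_steps):
            t_mid = (i + 0.5) * step
            alive = e_cur > 0
            if not alive.any():
                break
            loss = np.zeros(n_samples)
            loss[alive] = np.minimum(
                np.interp(e_cur[alive], e_dense, dedx) * step, e_cur[alive])
            pos = src + t_mid * u
            inside = (np.einsum("ij,ij->i", pos, pos) < rn * rn) & alive
            dep[inside] += loss[inside]
            e_cur -= loss
        total += yld * np.mean(dep * weight)
    return total * MEV_TO_J / sphere_mass_kg(rn)


class TestCrossSValue:
    def test_zero_beyond_alpha_reach(self, study_geo):
        spec = load_decay_chain("Ac-225", True)
        assert cross_svalue(120.0, study_geo, spec) == 0.0

    def test_nearest_neighbor_against_mc_oracle(self, study_geo):
        table = load_range_energy_table()
        spec = load_decay_chain("Ac-225", True)
        implementation = cross_svalue(12.0, study_geo, spec, "cell_surface",
                                      table)
        oracle = _mc_cross_svalue(12.0, study_geo, spec, table,
                                  n_samples=60_000, seed=1234)
        assert implementation == pytest.approx(oracle, rel=0.02)

    def test_full_chain_dominates_parent_kernel(self, kernels):
        full = kernels.kernel(True, "cell_surface")
        parent = kernels.kernel(False, "cell_surface")
        interp_full = np.interp(parent.cross_distances, full.cross_distances,
                                full.cross_values)
        assert np.all(interp_full >= parent.cross_values * (1 - 1e-9))

    def test_kernel_monotone_outside_bragg_windows(self, kernels, study_geo):
        # 1/r^2 geometry makes the kernel fall with distance except where a
        # line's track ends inside the nucleus: there the Bragg peak of the
        # stopping power produces a local rise just before the cutoff
        from spheradose.alpha_dosimetry import (load_decay_chain,
                                                load_range_energy_table)
        ker = kernels.kernel(True, "cell_surface")
        table = load_range_energy_table()
        spec = load_decay_chain("Ac-225", True)
        reaches = np.array([float(table.range(e)) for e, _ in spec.lines]) \
            + study_geo.cell_radius + study_geo.nucleus_radius
        d = ker.cross_distances
        in_window = np.any((d[:, None] > reaches - 25) &
                           (d[:, None] <= reaches), axis=1)
        rising = np.diff(ker.cross_values) > 1e-12
        assert not np.any(rising & ~in_window[:-1])
        # and the kernel maximum sits at the nearest lattice distance
        assert np.argmax(ker.cross_values) == 0

    def test_kernel_grid_symmetric(self, kernels):
        grid = kernels.kernel(True, "cell_surface").as_grid()
        for ax in (0, 1, 2):
            assert np.array_equal(grid, np.flip(grid, axis=ax))
        assert np.array_equal(grid, np.transpose(grid, (2, 0, 1)))

    def test_kernel_center_voxel_zero(self, kernels):
        grid = kernels.kernel(True, "cell_surface").as_grid()
        n = grid.shape[0] // 2
        assert grid[n, n, n] == 0.0
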