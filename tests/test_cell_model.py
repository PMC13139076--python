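"""Hepatocyte ODE system: algebraic identities, integrators, classification."""

import numpy as np
import pytest

import zonetox as zt
from zonetox.cell_model import StateThresholds, initial_state
from zonetox.errors import GridMismatchError, InvalidParameterError
from zonetox.lobule import ExposureField
from zonetox.zonation import MetabolicParameters, ZonationSpec


class TestRHS:
    def test_health_fractions_conserved_term_by_term(self):
        p = MetabolicParameters()
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.uniform(0, 1, 10) * np.array(
                [1e-13, 1e-13, 1e-14, 1e-16, 1e-14, 1e-14, 1, 1, 1, 1])
            dy = zt.rhs(y, p, plobule_forcing=1e-13)
            # zero up to round-off relative to the individual flux terms
            scale = max(abs(dy[6]), abs(dy[7]), abs(dy[8]), 1e-30)
            assert abs(dy[6] + dy[7] + dy[8]) <= 1e-12 * scale

    def test_gsh_steady_state(self):
        p = MetabolicParameters()
        y = initial_state(p)
        y[4] = p.bG / p.dG  # N = 0, C = 0 already
        dy = zt.rhs(y, p, plobule_forcing=0.0)
        assert dy[4] == pytest.approx(0.0, abs=1e-30)

    def test_no_drug_no_intracellular_flux(self):
        p = MetabolicParameters()
        y = initial_state(p)
        dy = zt.rhs(y, p, plobule_forcing=0.0)
        assert dy[1] == 0.0  # Pin
        assert dy[3] == 0.0  # NAPQI

    def test_negative_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            MetabolicParameters(ku=-1.0)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(InvalidParameterError):
            zt.rhs(np.full(10, np.nan), MetabolicParameters(), 0.0)


class TestIntegrateCell:
    def test_zero_exposure_stays_healthy(self):
        p = MetabolicParameters()
        t_out = np.linspace(0, 86400, 25)
        traj = zt.integrate_cell(p, None, t_out, rtol=1e-8)
        assert np.allclose(traj["H"], 1.0, atol=1e-9)
        assert np.allclose(traj["L"], 0.0, atol=1e-9)

    def test_local_pool_exponential_decay(self):
        # the extracellular pool in local mode empties first order at ku
        p = MetabolicParameters()
        t_half = np.log(2) / p.ku
        t_out = np.linspace(0, 1.2 * t_half, 40)
        traj = zt.integrate_cell(p, 1.0, t_out, rtol=1e-9,
                                 mode="local_pool")
        expected = np.exp(-p.ku * t_out)
        assert np.allclose(traj["Plob"], expected, rtol=1e-6)
        i = np.argmin(np.abs(t_out - t_half))
        assert traj["Plob"][i] == pytest.approx(expected[i], rel=1e-6)

    def test_gsh_relaxation_closed_form(self):
        # with no drug, G relaxes to bG/dG at rate dG
        p = MetabolicParameters(G0=2.0e-15)
        t_out = np.linspace(0, 3 / p.dG, 30)
        traj = zt.integrate_cell(p, None, t_out, rtol=1e-9)
        g_inf = p.bG / p.dG
        expected = g_inf + (p.G0 - g_inf) * np.exp(-p.dG * t_out)
        assert np.allclose(traj["G"], expected, rtol=1e-6)

    def test_t_out_outside_exposure_grid_rejected(self):
        t = np.linspace(0, 100, 11)
        with pytest.raises(GridMismatchError):
            zt.integrate_cell(MetabolicParameters(), (t, np.ones_like(t)),
                              np.linspace(0, 200, 5))


class TestClassification:
    def test_fully_lysed_is_necrosed(self):
        y = np.zeros(10)
        y[8] = 1.0
        assert zt.classify_cell(y) == "necrosed"

    def test_pristine_cell_is_healthy(self):
        assert zt.classify_cell(initial_state(MetabolicParameters())) \
            == "healthy"

    def test_lysis_dominates_rule_order(self):
        y = np.zeros(10)
        y[6], y[7], y[8] = 0.3, 0.3, 0.6
        assert zt.classify_cell(y) == "necrosed"

    def test_damaged_beats_regenerated(self):
        y = np.zeros(10)
        y[7], y[9] = 0.3, 0.2
        assert zt.classify_cell(y) == "damaged"

    def test_thresholds_config_exposed(self):
        y = np.zeros(10)
        y[8] = 0.4
        assert zt.classify_cell(y, StateThresholds(necrosed_L=0.3)) \
            == "necrosed"


def _uniform_exposure(n_cells, value=2e-13, horizon=7200.0, dt=300.0):
    t = np.arange(0.0, horizon + dt, dt)
    return ExposureField(t=t, c=np.full((n_cells, len(t)), value))


class TestRunLobule:
    def test_uniform_conditions_give_identical_trajectories(self):
        lat = zt.build_lattice(24)
        field = zt.build_parameter_field(ZonationSpec("H1", 0.0), lat)
        res = zt.run_lobule(lat, field, _uniform_exposure(24),
                            batch_dt=5.0, output_dt=600.0)
        assert np.all(res.states == res.states[0])

    def test_permuting_cells_permutes_outputs(self):
        lat = zt.build_lattice(12)
        field = zt.build_parameter_field(ZonationSpec("H1", 0.8), lat)
        exposure = _uniform_exposure(12)
        # graded exposure so rows differ
        exposure = ExposureField(t=exposure.t,
                                 c=exposure.c * (1 + lat.x)[:, None])
        res = zt.run_lobule(lat, field, exposure, batch_dt=5.0,
                            output_dt=600.0)
        perm = np.random.default_rng(0).permutation(12)
        res_p = zt.run_lobule(lat, field.iloc[perm],
                              ExposureField(t=exposure.t,
                                            c=exposure.c[perm]),
                              batch_dt=5.0, output_dt=600.0)
        assert np.array_equal(res_p.states, res.states[perm])

    def test_zero_exposure_no_necrosis(self):
        lat = zt.build_lattice(9)
        field = zt.build_parameter_field(ZonationSpec("H1", 0.0), lat)
        res = zt.run_lobule(lat, field, _uniform_exposure(9, value=0.0),
                            batch_dt=5.0, output_dt=600.0)
        assert res.necrosed_series().sum() == 0

    def test_mismatched_shapes_rejected(self):
        lat = zt.build_lattice(6)
        field = zt.build_parameter_field(ZonationSpec("H1", 0.0), lat)
        with pytest.raises(GridMismatchError):
            zt.run_lobule(lat, field, _uniform_exposure(5))

    def test_regeneration_monotone_on_full_run(self, baseline_results):
        R = baseline_results["D"].states[..., 9]
        assert np.all(np.diff(R, axis=1) >= -1e-9)

    def test_batch_matches_radau_on_real_forcing(self, small_lattice,
                                                 small_config,
                                                 baseline_results):
        # cross-validation of the fixed-step batch kernel against the
        # adaptive implicit single-cell path on the strongest-exposed cell
        res = baseline_results["D"]
        pat = zt.patient_fixtures()[3]
        series = zt.simulate_pbpk(pat, small_config.pbpk,
                                  small_config.pbpk_dt)
        exposure = zt.transport_exposure(series, small_lattice,
                                         small_config.transport,
                                         scale=small_config.exposure_scale)
        traj = zt.integrate_cell(zt.MetabolicParameters(),
                                 (exposure.t, exposure.c[0]), res.t,
                                 rtol=1e-8)
        scale = np.abs(traj.states).max(axis=0)
        scale[scale == 0] = 1.0
        err = np.abs(res.states[0] - traj.states) / scale
        assert err.max() < 1e-4
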