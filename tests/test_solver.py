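"""Integration, steady-state convergence, conservation and determinism."""

import numpy as np
import pytest

import perfusim as ps
from perfusim.network import compartment_derivatives, build_topology
from perfusim.solver import ModelAssembly, SolverSettings, check_conservation, simulate


class TestDeterminism:
    def test_two_runs_bitwise_identical(self, params, fast_settings):
        a = simulate(params, settings=fast_settings)
        b = simulate(params, settings=fast_settings)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.aux, b.aux)
        assert a.beats_run == b.beats_run


class TestAccuracy:
    def test_step_refinement_changes_cycle_mean_below_01_percent(self, params):
        coarse = simulate(params, settings=SolverSettings(dt_max=2e-4, min_beats=8, max_beats=40))
        fine = simulate(params, settings=SolverSettings(dt_max=1e-4, min_beats=8, max_beats=40))
        a, b = coarse.cycle_mean("AoP"), fine.cycle_mean("AoP")
        assert abs(a - b) / abs(b) < 1e-3

    def test_valve_smoothing_width_insensitive(self, params):
        ref = simulate(params, settings=SolverSettings(min_beats=8, max_beats=40))
        half = simulate(params, settings=SolverSettings(min_beats=8, max_beats=40,
                                                        eps_valve=5e-4))
        assert abs(ref.cycle_mean("AoP") - half.cycle_mean("AoP")) / ref.cycle_mean("AoP") < 1e-3

    def test_kernel_matches_reference_derivatives(self, params):
        """The compiled RHS agrees with the plain-python network equations."""
        asm = ModelAssembly(params)
        x = asm.initial_state()
        dx, aux = asm.rhs(0.123, x)
        topo = build_topology(params)
        boundary = {name: aux[i] for i, name in enumerate(("LV", "RV", "LA", "RA"))}
        ref = compartment_derivatives(np.concatenate([x[4:22], x[22:]]), topo, boundary)
        # smoothed vs ideal diode flows differ only near zero pressure gradient
        assert np.allclose(ref[:18], dx[4:22], atol=1e-3)
        assert np.allclose(ref[18:], dx[22:], atol=1e-8)


class TestConservation:
    def test_volume_drift_below_01_percent_over_60s(self, params):
        settings = SolverSettings(min_beats=90, max_beats=90)
        rec = simulate(params, settings=settings, record="all")
        assert rec.time[-1] - rec.time[0] > 58.0
        report = check_conservation(rec)
        assert report["max_relative_drift"] < 1e-3

    def test_single_beat_drift_below_001_percent(self, params):
        rec = simulate(params, settings=SolverSettings(min_beats=2, max_beats=2), record="all")
        one_beat = rec.total_volume()[:rec.samples_per_beat]
        drift = np.max(np.abs(one_beat - one_beat[0])) / one_beat[0]
        assert drift < 1e-4

    def test_broken_flow_sign_is_flagged(self, params, fast_settings):
        """A record with a corrupted volume trace must show drift > 1%."""
        rec = simulate(params, settings=fast_settings)
        rec.states = rec.states.copy()
        rec.states[rec.samples_per_beat:, 4] += 0.03 * rec.total_volume()[0]
        report = check_conservation(rec)
        assert report["max_relative_drift"] > 0.01


class TestSteadyState:
    @pytest.mark.parametrize("column", ["LVP", "AoP", "PAP"])
    def test_periodicity_of_converged_waveforms(self, baseline_record, column):
        rec = baseline_record
        assert rec.converged
        n = rec.samples_per_beat
        last, prev = rec.column(column)[-n:], rec.column(column)[-2 * n:-n]
        rng = np.ptp(last)
        assert np.max(np.abs(last - prev)) / rng < 0.01

    def test_start_phase_invariance(self, params):
        s1 = SolverSettings(min_beats=20, max_beats=120)
        s2 = SolverSettings(min_beats=20, max_beats=120, start_phase=0.45)
        a = simulate(params, settings=s1)
        b = simulate(params, settings=s2)
        for col in ("AoP", "LAP", "RAP"):
            ma, mb = a.cycle_mean(col), b.cycle_mean(col)
            assert abs(ma - mb) / abs(ma) < 1e-3
        assert abs(a.cardiac_output() - b.cardiac_output()) / a.cardiac_output() < 1e-3

    def test_valves_never_regurgitate(self, baseline_record):
        for v in ("Q_MV", "Q_AV", "Q_TV", "Q_PV"):
            assert np.min(baseline_record.column(v)) >= 0.0

    def test_volumes_stay_positive(self, baseline_record):
        n_vol = sum(n.startswith("V_") for n in baseline_record.state_names)
        assert np.min(baseline_record.states[:, :n_vol]) >= 0.0

    def test_lv_loop_traversed_counter_clockwise(self, baseline_record):
        loop = ps.extract_pv_loop(baseline_record, "LV")
        assert loop.signed_area() > 0.0


class TestErrorHandling:
    def test_nan_state_names_first_bad_variable(self, params):
        bad = params.model_copy(deep=True)
        bad.compartments["AA2"].L = 1e-9     # stiffness far below the fixed step
        with pytest.raises(FloatingPointError, match="t="):
            simulate(bad, settings=SolverSettings(min_beats=4, max_beats=8))

    def test_wrong_initial_state_dimension_rejected(self, params, fast_settings):
        with pytest.raises(ps.ConfigurationError, match="dimension"):
            simulate(params, settings=fast_settings, initial_state=np.zeros(5))
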