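"""Room-kinetics generator: steady states, limits, events, determinism."""

import numpy as np
import pytest

from rnaero.nuclide_chain import InvalidInputError
from rnaero.size_distribution import gm_gsd
from rnaero.synthetic_room import (
    Event,
    EventScript,
    RoomConfig,
    simulate_room,
    steady_state,
    steady_state_fun,
)


class TestConfigValidation:
    def test_deposition_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            RoomConfig(lambda_dep_un=0.1, lambda_dep_att=0.2)

    def test_bad_recoil_rejected(self):
        with pytest.raises(InvalidInputError):
            RoomConfig(recoil_prob=1.5)

    def test_overlapping_events_rejected(self):
        with pytest.raises(InvalidInputError):
            EventScript((Event("candle", 1.0, 3.0), Event("candle", 2.0, 4.0)))


class TestSteadyState:
    def test_no_attachment_gives_fun_one(self):
        cfg = RoomConfig(beta=0.0)
        assert steady_state_fun(cfg) == pytest.approx(1.0)

    def test_fun_decreasing_in_surface(self):
        cfg = RoomConfig()
        s_values = np.geomspace(1e6, 1e10, 12)
        funs = [steady_state_fun(cfg, s_tot=s) for s in s_values]
        assert all(b < a for a, b in zip(funs, funs[1:]))
        assert funs[-1] < 0.02  # strong attachment drives f_un small

    def test_surface_not_number_controls_fun(self):
        # two spectra with the same particle number but different surface
        # must give different f_un; equal surface gives equal f_un
        cfg = RoomConfig()
        s_small = 5120.0 * np.pi * 20.0**2   # all particles at 20 nm
        s_large = 5120.0 * np.pi * 200.0**2  # same number at 200 nm
        f_small = steady_state_fun(cfg, s_tot=s_small)
        f_large = steady_state_fun(cfg, s_tot=s_large)
        assert f_small > f_large

    def test_default_quiescent_fun_in_observed_range(self):
        # indoor quiescent campaigns report f_un between 0.09 and 0.28
        f = steady_state_fun(RoomConfig())
        assert 0.09 <= f <= 0.28

    def test_entry_rate_mode(self):
        cfg = RoomConfig(c_rn_fixed=None, radon_entry_rate=70.0)
        ss = steady_state(cfg)
        assert ss["c_rn"] > 0


class TestSimulation:
    def test_matches_closed_form_at_48h(self):
        cfg = RoomConfig(baseline_total_gsd=1.0, seed=3)
        run = simulate_room(cfg, duration_h=48.0, dt_s=60.0, init="zero")
        assert run.states["f_un"].iloc[-1] == pytest.approx(
            steady_state_fun(cfg), rel=0.01)

    def test_random_configs_match_closed_form(self, rng):
        for _ in range(3):
            cfg = RoomConfig(
                baseline_total_gsd=1.0,
                lambda_v_closed=float(rng.uniform(0.1, 1.0)),
                beta=float(rng.uniform(0.5e-7, 3e-7)),
                lambda_dep_un=float(rng.uniform(10, 30)),
                recoil_prob=float(rng.uniform(0, 1)),
                seed=4,
            )
            run = simulate_room(cfg, duration_h=48.0, dt_s=60.0, init="zero")
            assert run.states["f_un"].iloc[-1] == pytest.approx(
                steady_state_fun(cfg), rel=0.01)

    def test_no_attachment_simulated_fun_is_one(self):
        cfg = RoomConfig(beta=0.0, baseline_total_gsd=1.0, seed=5)
        run = simulate_room(cfg, duration_h=6.0, dt_s=60.0)
        assert np.allclose(run.states["f_un"], 1.0)

    def test_strong_ventilation_flushes_room(self):
        cfg = RoomConfig(c_rn_fixed=None, radon_entry_rate=0.0, outdoor_radon=0.0,
                         lambda_v_closed=50.0, baseline_total_gsd=1.0, seed=6)
        run = simulate_room(cfg, duration_h=4.0, dt_s=30.0)
        last = run.states.iloc[-1]
        assert last["C_Rn"] < 1e-6
        assert last[["A_Po218_un", "A_Pb214_att"]].max() < 1e-6

    def test_secular_equilibrium_without_removal(self):
        cfg = RoomConfig(lambda_v_closed=0.0, beta=0.0, lambda_dep_un=1e-12,
                         lambda_dep_att=0.0, baseline_total_gsd=1.0, seed=7)
        run = simulate_room(cfg, duration_h=24.0, dt_s=60.0, init="zero")
        last = run.states.iloc[-1]
        for nuc in ("Po218", "Pb214", "Bi214"):
            total = last[f"A_{nuc}_un"] + last[f"A_{nuc}_att"]
            assert total == pytest.approx(last["C_Rn"], rel=1e-3)

    def test_deterministic_given_seed(self, tmp_path):
        cfg = RoomConfig(seed=9)
        script = EventScript((Event("toaster", 2.0, 2.3),))
        out1, out2 = tmp_path / "a", tmp_path / "b"
        simulate_room(cfg, script, duration_h=5.0, dt_s=60.0).write(out1)
        simulate_room(cfg, script, duration_h=5.0, dt_s=60.0).write(out2)
        for name in ("smps.csv", "eqf.csv", "true_state.csv", "manifest.yaml"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_quiescent_emitted_gm_gsd(self):
        # long quiescent run reproduces the configured lognormal baseline
        cfg = RoomConfig(seed=7)
        run = simulate_room(cfg, duration_h=120.0, dt_s=60.0)
        st = gm_gsd(run.smps.sum(axis=1))
        assert st.gm == pytest.approx(cfg.baseline_total_gm, rel=0.05)
        assert st.gsd == pytest.approx(cfg.baseline_total_gsd, rel=0.05)

    def test_candle_event_raises_ctot_and_lowers_fun(self):
        cfg = RoomConfig(baseline_total_gsd=1.0, seed=8)
        script = EventScript((Event("candle", 4.0, 10.0),))
        run = simulate_room(cfg, script, duration_h=16.0, dt_s=30.0)
        states = run.states
        pre = states[states["time_h"] < 4.0]
        during = states[(states["time_h"] >= 6.0) & (states["time_h"] < 10.0)]
        assert during["C_tot"].mean() > 50 * pre["C_tot"].mean()
        assert during["f_un"].iloc[-1] < pre["f_un"].iloc[-1]

    def test_fun_step_response_settles_on_progeny_timescale(self):
        # f_un relaxation after a surface-area step is governed by the
        # slow attached Pb/Bi inventories: settling takes tens of minutes
        from rnaero.synthetic_room import fun_step_response

        for factor in (0.5, 2.0):
            resp = fun_step_response(RoomConfig(), s_factor=factor)
            assert resp["t90"] > 10.0 / 60.0
            assert resp["mean_relaxation"] > 10.0 / 60.0
        up = fun_step_response(RoomConfig(), s_factor=2.0)
        assert up["f_inf"] < up["f0"]  # more surface -> lower f_un

    def test_window_open_increases_ventilation_loss(self):
        cfg = RoomConfig(c_rn_fixed=None, baseline_total_gsd=1.0, seed=10)
        script = EventScript((Event("window_open", 6.0, 12.0),))
        run = simulate_room(cfg, script, duration_h=14.0, dt_s=60.0)
        states = run.states
        pre = states[(states["time_h"] >= 4.0) & (states["time_h"] < 6.0)]
        open_win = states[(states["time_h"] >= 10.0) & (states["time_h"] < 12.0)]
        assert open_win["C_Rn"].mean() < 0.5 * pre["C_Rn"].mean()

    def test_emission_cadences(self, quiet_run):
        _, run = quiet_run
        dt_smps = np.diff(run.smps.index.to_numpy()).astype("timedelta64[s]")
        assert np.all(dt_smps == np.timedelta64(240, "s"))
        dt_eqf = np.diff(run.eqf.index.to_numpy()).astype("timedelta64[s]")
        assert np.all(dt_eqf == np.timedelta64(7200, "s"))

    def test_states_nonnegative(self, quiet_run):
        _, run = quiet_run
        assert (run.states.select_dtypes("number") >= 0).all().all()

    @pytest.mark.parametrize("kwargs", [
        {"dt_s": 120.0}, {"duration_h": 0.5}, {"init": "bogus"},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(InvalidInputError):
            simulate_room(RoomConfig(), **kwargs)
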