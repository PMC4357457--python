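"""Tests of the closed-loop circulation model."""

import numpy as np
import pytest

from afsim.indices import summarize
from afsim.model import (
    SolverOptions,
    build_initial_state,
    chamber_pressure,
    derivatives,
    simulate,
    systolic_duration,
    valve_flow,
    ventricular_activation,
)
from afsim.parameters import default_params, load_params, save_params
from afsim.rr import sample_rr


class TestActivation:
    def test_zero_at_beat_onset(self):
        assert ventricular_activation(0.0, 1.2) == 0.0

    def test_peaks_at_one(self):
        rr = 1.2
        t = np.linspace(0, rr, 4000, endpoint=False)
        a = [ventricular_activation(ti, rr) for ti in t]
        assert max(a) == pytest.approx(1.0, abs=1e-5)

    def test_systolic_fraction_grows_at_short_rr(self):
        k = default_params().tsys_k
        assert systolic_duration(0.46, k) / 0.46 > systolic_duration(1.2, k) / 1.2

    def test_outside_beat_rejected(self):
        with pytest.raises(ValueError):
            ventricular_activation(1.3, 1.2)
        with pytest.raises(ValueError):
            ventricular_activation(-0.1, 1.2)


class TestChamberPressure:
    def test_zero_at_unstressed_volume(self):
        for act in (0.0, 0.5, 1.0):
            assert chamber_pressure(10.0, act, 0.1, 2.5, 10.0) == 0.0

    def test_passive_atrium_ignores_activation(self):
        vals = {chamber_pressure(60.0, a, 0.2, 0.2, 14.0, passive=True)
                for a in (0.0, 0.3, 1.0)}
        assert len(vals) == 1

    def test_peak_systolic_value(self):
        assert chamber_pressure(55.0, 1.0, 0.1, 2.5, 5.0) == pytest.approx(125.0)


class TestValveFlow:
    def test_closed_under_adverse_gradient(self):
        assert valve_flow(10.0, 80.0, 0.01) == 0.0

    def test_ohmic_when_open(self):
        assert valve_flow(81.0, 80.0, 0.01) == pytest.approx(100.0)

    @pytest.mark.parametrize("p_up,p_down", [(0, 0), (-5, 3), (50, 49.9), (200, 0)])
    def test_never_regurgitant(self, p_up, p_down):
        assert valve_flow(p_up, p_down, 0.01) >= 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            valve_flow(np.nan, 0.0, 0.01)


class TestDerivatives:
    def test_closed_loop_conserves_volume_at_random_states(self):
        params = default_params()
        rng = np.random.default_rng(0)
        base = build_initial_state(params)
        for _ in range(25):
            y = base * rng.uniform(0.8, 1.2, 12)
            dy = derivatives(0.2, y, params, 0.9)
            assert abs(dy[:8].sum()) < 1e-9 * np.abs(dy[:8]).max()

    def test_isovolumic_when_valves_shut(self):
        params = default_params()
        y = build_initial_state(params)
        y[8:] = 0.0  # no transvalvular flow
        # mid-systole: LV pressure far above atrium, below aorta impossible,
        # so force an adverse aortic gradient via a high arterial volume
        y[4] = params.sa_v0 + 200.0 * params.sa_c
        dy = derivatives(0.05, y, params, 1.0)
        assert dy[1] == 0.0

    def test_filling_raises_lv_volume(self):
        params = default_params()
        y = build_initial_state(params)
        y[8] = 50.0  # open mitral carrying forward flow
        y[9:] = 0.0
        dy = derivatives(0.95, y, params, 1.0)
        assert dy[1] == pytest.approx(50.0)

    def test_non_finite_state_named(self):
        params = default_params()
        y = build_initial_state(params)
        y[1] = np.nan
        with pytest.raises(ValueError, match="v_lv"):
            derivatives(0.0, y, params, 1.0)


class TestSimulate:
    def test_periodic_steady_state_at_regular_rhythm(self):
        seq = sample_rr(200, 50, cv=0.0)
        trace = simulate(seq)
        df = summarize(trace)
        sv = df["sv"].to_numpy()[-50:]
        assert np.abs(np.diff(sv) / sv[:-1]).max() < 1e-3

    def test_blood_volume_conserved(self, short_regular_trace):
        assert short_regular_trace.volume_drift < 1e-9

    def test_no_regurgitation_anywhere(self, short_regular_trace):
        for q in short_regular_trace.flows.values():
            assert q.min() >= 0.0

    def test_valve_event_ordering(self, short_regular_trace):
        df = summarize(short_regular_trace)
        qao = short_regular_trace.y[:, 9]
        t = short_regular_trace.t
        for _, row in df.iloc[5:15].iterrows():
            # aortic closure must postdate an opening within the same beat
            sel = (t >= row["t_ed"]) & (t <= row["t_es"])
            assert qao[sel].max() > 1.0
        # diastole follows systole: the mitral closure beginning each beat
        # lies after the previous beat's aortic closure
        assert (df["t_ed"].to_numpy()[1:] > df["t_es"].to_numpy()[:-1]).all()

    def test_step_halving_leaves_stroke_volume_unchanged(self):
        seq = sample_rr(100, 70, cv=0.24, seed=21)
        sv = []
        for dt in (2e-4, 1e-4):
            trace = simulate(seq, solver=SolverOptions(dt=dt))
            sv.append(summarize(trace)["sv"].mean())
        assert abs(sv[1] - sv[0]) / sv[0] < 0.005

    def test_fixed_step_matches_adaptive_reference(self):
        # independent integration route: scipy's adaptive RK45
        seq = sample_rr(10, 70, cv=0.0)
        t1 = simulate(seq)
        t2 = simulate(seq, solver=SolverOptions(method="RK45", rtol=1e-8, atol=1e-10))
        assert np.max(np.abs(t1.y[:, 1] - t2.y[:, 1])) < 0.05  # mL, LV volume

    def test_textbook_normal_baseline_at_70_bpm(self, short_regular_trace):
        df = summarize(short_regular_trace).iloc[10:]
        ef = df["ef"].mean()
        psyst = df["p_sas_syst"].mean()
        assert 55.0 <= ef <= 70.0
        assert 100.0 <= psyst <= 130.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            simulate(np.array([]))


class TestParameters:
    def test_initial_state_sums_to_total_volume(self):
        params = default_params()
        y = build_initial_state(params)
        assert y[:8].sum() == pytest.approx(params.total_volume)

    def test_yaml_round_trip(self, tmp_path):
        p = default_params()
        path = tmp_path / "p.yaml"
        save_params(p, path)
        assert load_params(path) == p

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "p.yaml"
        path.write_text("lv_emax: 2.0\nbogus_key: 1.0\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_params(path)

    def test_invalid_elastance_ordering_rejected(self):
        with pytest.raises(ValueError):
            default_params().replace(lv_emax=0.01)
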