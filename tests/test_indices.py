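"""Tests of per-beat index extraction and aggregation."""

import numpy as np
import pandas as pd
import pytest

from afsim.fixtures import AnalyticBeatSpec, make_analytic_beat
from afsim.indices import (
    MMHG_ML_TO_J,
    aggregate,
    beat_energetics,
    locate_es_ed,
    pv_loop_area,
    segment_beats,
    summarize,
)
from afsim.model import simulate
from afsim.rr import sample_rr


class TestLoopArea:
    def test_rectangle(self):
        p = np.r_[np.full(100, 10.0), np.linspace(10, 100, 100),
                  np.full(100, 100.0), np.linspace(100, 10, 100)]
        v = np.r_[np.linspace(50, 130, 100), np.full(100, 130.0),
                  np.linspace(130, 50, 100), np.full(100, 50.0)]
        assert pv_loop_area(p, v) == pytest.approx(0.95992, rel=1e-3)

    def test_ellipse(self):
        th = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        p = 55 + 45 * np.sin(th)
        v = 90 + 40 * np.cos(th)
        exact = np.pi * 45 * 40 * MMHG_ML_TO_J
        assert pv_loop_area(p, v) == pytest.approx(exact, rel=1e-3)

    def test_triangle(self):
        p = np.array([10.0, 10.0, 100.0])
        v = np.array([50.0, 130.0, 50.0])
        exact = 0.5 * 80 * 90 * MMHG_ML_TO_J
        assert pv_loop_area(p, v) == pytest.approx(exact, rel=1e-12)

    def test_orientation_invariance(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        p, v = 55 + 45 * np.sin(th), 90 + 40 * np.cos(th)
        assert pv_loop_area(p, v) == pytest.approx(pv_loop_area(p[::-1], v[::-1]))

    def test_degenerate_loop_is_zero(self):
        assert pv_loop_area(np.full(10, 5.0), np.full(10, 7.0)) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pv_loop_area(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestEsEdLocation:
    def test_planted_events_recovered(self):
        beat, _ = make_analytic_beat(AnalyticBeatSpec(t_es=0.30, t_ed=0.95))
        t_es, t_ed = locate_es_ed(beat)
        assert t_es == pytest.approx(0.30, abs=1e-6)
        assert t_ed == pytest.approx(0.95, abs=1e-6)

    def test_non_ejecting_beat_flagged(self):
        beat, _ = make_analytic_beat(AnalyticBeatSpec())
        beat.q_ao_raw = np.full_like(beat.q_ao_raw, -1.0)
        beat.events = {}
        with pytest.raises(ValueError, match="never opened"):
            locate_es_ed(beat)

    def test_volume_drops_from_ed_to_es_in_simulation(self):
        seq = sample_rr(30, 70, cv=0.0)
        df = summarize(simulate(seq))
        assert (df["v_lved"] > df["v_lves"]).all()


class TestEnergetics:
    def test_stroke_volume_and_fraction(self):
        out = beat_energetics(
            v_lved=126.4, v_lves=48.94, p_lved=15.46, p_lves=91.75,
            sw_j=0.88, p_lv_mean=33.92, p_sas_syst=103.8, rr=1.2,
        )
        assert out["sv"] == pytest.approx(77.46, abs=1e-6)
        out2 = beat_energetics(
            v_lved=100.0, v_lves=50.0, p_lved=10.0, p_lves=90.0,
            sw_j=0.9, p_lv_mean=30.0, p_sas_syst=100.0, rr=1.0,
        )
        assert out2["ef"] == pytest.approx(50.0)

    def test_potential_energy_formula(self):
        # hand arithmetic: 91.75*43.94/2 - 15.46*121.4/4 = 1546.5365 mmHg.mL
        out = beat_energetics(
            v_lved=126.4, v_lves=48.94, p_lved=15.46, p_lves=91.75,
            sw_j=0.88, p_lv_mean=33.92, p_sas_syst=103.8, rr=1.2,
        )
        assert out["pe"] == pytest.approx(1546.5365 * MMHG_ML_TO_J, rel=1e-6)
        assert out["pe"] == pytest.approx(0.2062, abs=5e-4)

    def test_rate_scaled_indices_use_instantaneous_rate(self):
        out = beat_energetics(
            v_lved=120.0, v_lves=60.0, p_lved=12.0, p_lves=90.0,
            sw_j=0.8, p_lv_mean=40.0, p_sas_syst=110.0, rr=0.5,
        )
        assert out["co"] == pytest.approx(60.0 * 120.0 / 1000.0)
        assert out["rpp"] == pytest.approx(110.0 * 120.0)
        assert out["tti"] == pytest.approx(40.0 * 0.5)
        assert out["tti_min"] == pytest.approx(40.0 * 60.0)

    def test_invalid_edv_rejected(self):
        with pytest.raises(ValueError):
            beat_energetics(
                v_lved=0.0, v_lves=0.0, p_lved=0.0, p_lves=0.0,
                sw_j=0.0, p_lv_mean=0.0, p_sas_syst=0.0, rr=1.0,
            )


class TestSegmentation:
    def test_one_slice_per_beat_partitioning(self):
        seq = sample_rr(25, 70, cv=0.24, seed=4)
        trace = simulate(seq)
        beats = segment_beats(trace)
        assert len(beats) == 25
        # slice durations equal the RR draws to within one sample spacing
        for b in beats:
            spacing = b.t[1] - b.t[0]
            assert len(b.t) * spacing == pytest.approx(b.rr, abs=2 * spacing)
        # concatenation reconstructs the analyzed trace
        assert sum(len(b.t) for b in beats) == len(trace.t)


class TestAggregation:
    def test_two_point_statistics(self):
        df = pd.DataFrame({"sv": [70.0, 80.0]})
        agg = aggregate(df)
        assert agg.loc["sv", "mean"] == pytest.approx(75.0)
        assert agg.loc["sv", "sd"] == pytest.approx(np.sqrt(50.0))

    def test_mean_linearity_of_stroke_volume(self, af_run_50):
        agg = af_run_50.agg
        assert agg.loc["sv", "mean"] == pytest.approx(
            agg.loc["v_lved", "mean"] - agg.loc["v_lves", "mean"], rel=1e-9
        )

    def test_mean_ef_is_mean_of_ratios(self, af_run_50):
        agg = af_run_50.agg
        ratio_of_means = agg.loc["sv", "mean"] / agg.loc["v_lved", "mean"] * 100
        assert agg.loc["ef", "mean"] != pytest.approx(ratio_of_means, abs=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"sv": rng.normal(75, 8, 200), "ef": rng.normal(60, 5, 200)})
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(aggregate(df), aggregate(shuffled))

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame({"sv": [70.0]}))


class TestInvariantsOnSimulatedBeats:
    def test_pva_bounds_efficiency(self, af_run_50):
        df = af_run_50.summary
        ej = df[df["ejecting"]]
        assert (ej["pva"] >= ej["sw"] - 1e-12).all()
        assert (ej["sw_pva"] <= 100.0).all()
        assert (ej["sw_pva"] > 0.0).all()

    def test_jensen_direction_for_rate_products(self, af_run_50):
        df = af_run_50.summary
        nominal = 50.0
        assert df["hr_inst"].mean() > nominal
        assert df["rpp"].mean() > df["p_sas_syst"].mean() * nominal
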