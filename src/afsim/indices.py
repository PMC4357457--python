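"""Per-beat hemodynamic and mechano-energetic indices.

A simulated trace is segmented at activation onsets; within each beat,
end-systole (es) is the instant the aortic valve closes and end-diastole
(ed) the instant the mitral valve closes.  From the es/ed samples and the
left-ventricular pressure-volume loop the module derives, per beat: stroke
volume SV, ejection fraction EF, stroke work SW (PV-loop area), elastic
potential energy PE, pressure-volume area PVA = PE + SW (an oxygen
consumption surrogate), cardiac output CO, rate pressure product RPP,
tension-time index TTI, and ventricular efficiency SW/PVA.

Rate-scaled indices (CO, RPP, TTI/min, PVA/min) use the *instantaneous*
rate 60/RR of the individual beat; with irregular rhythm the average of
such products exceeds the product of averages (Jensen's inequality), which
is the convention that matches whole-cohort reporting of these indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BeatTrace

__all__ = [
    "MMHG_ML_TO_J",
    "LV_UNSTRESSED_ML",
    "Beat",
    "segment_beats",
    "locate_es_ed",
    "pv_loop_area",
    "beat_energetics",
    "summarize",
    "aggregate",
    "write_summary_csv",
]

#: Energy conversion: 1 mmHg.mL in joules.
MMHG_ML_TO_J = 1.33322e-4

#: Unstressed left ventricular volume (mL) used in the PE formula.
LV_UNSTRESSED_ML = 5.0

#: A valve with peak flow below this (mL/s) never opened in the beat.
_OPEN_THRESHOLD = 1.0


@dataclass
class Beat:
    """One beat's slice of a trace, with valve-event bookkeeping.

    ``q_ao_raw``/``q_mi_raw`` are the *unrectified* inertial flow states:
    their downward zero crossings are the valve closure instants.
    """

    t: np.ndarray
    rr: float
    p_la: np.ndarray
    p_lv: np.ndarray
    p_sas: np.ndarray
    p_pas: np.ndarray
    p_pvn: np.ndarray
    v_la: np.ndarray
    v_lv: np.ndarray
    q_mi_raw: np.ndarray
    q_ao_raw: np.ndarray
    events: dict = field(default_factory=dict)

    @property
    def t0(self) -> float:
        return float(self.t[0])


def segment_beats(trace: BeatTrace) -> list[Beat]:
    """Split a trace into per-beat slices at the activation-onset markers.

    Warm-up beats were already discarded by the simulator; the returned
    slices partition the analyzed trace exactly.
    """
    if trace.beat_start.size == 0:
        raise ValueError("trace carries no beat-onset markers")
    P = trace.pressures
    V = trace.volumes
    bounds = np.r_[trace.beat_start, len(trace.t)]
    beats = []
    for i in range(trace.n_beats):
        sl = slice(bounds[i], bounds[i + 1])
        beats.append(
            Beat(
                t=trace.t[sl],
                rr=float(trace.rr[i]),
                p_la=P["p_la"][sl],
                p_lv=P["p_lv"][sl],
                p_sas=P["p_sas"][sl],
                p_pas=P["p_pas"][sl],
                p_pvn=P["p_pvn"][sl],
                v_la=V["v_la"][sl],
                v_lv=V["v_lv"][sl],
                q_mi_raw=trace.y[sl, 8],
                q_ao_raw=trace.y[sl, 9],
            )
        )
    return beats


def _down_crossing(
    t: np.ndarray, q: np.ndarray, which: str = "first", start: int = 0
) -> float | None:
    """Time of a downward zero crossing of ``q`` at/after ``start``
    (linear interpolation between samples); ``which`` picks the first or
    the last crossing."""
    qs = q[start:]
    sign = qs > 0.0
    idx = np.flatnonzero(sign[:-1] & ~sign[1:])
    if idx.size == 0:
        return None
    i = start + (idx[0] if which == "first" else idx[-1])
    q0, q1 = q[i], q[i + 1]
    frac = q0 / (q0 - q1) if q0 != q1 else 0.0
    return float(t[i] + frac * (t[i + 1] - t[i]))


def locate_es_ed(beat: Beat) -> tuple[float, float]:
    """Locate end-systole and end-diastole inside one beat.

    es is the aortic-valve closure (downward zero crossing of the aortic
    flow state after it opened); ed is the mitral closure that seals the
    ventricle as this beat's contraction begins — the first mitral closure
    in the beat, or the beat onset itself if the valve was already shut.

    Raises ``ValueError`` for a non-ejecting beat (aortic valve never
    opened); callers flag such beats rather than scoring them.
    """
    if beat.events:
        return beat.events["t_es"], beat.events["t_ed"]
    if beat.q_ao_raw.max() < _OPEN_THRESHOLD:
        raise ValueError("aortic valve never opened in this beat")
    # Aortic closure = the *final* cessation of forward aortic flow in the
    # beat (early systolic flow may ring against the arterial impedance).
    t_es = _down_crossing(beat.t, beat.q_ao_raw, which="last")
    if t_es is None:  # closure not completed within the slice: use last sample
        t_es = float(beat.t[-1])
    if beat.q_mi_raw[0] > 0.0:
        t_ed = _down_crossing(beat.t, beat.q_mi_raw, which="first")
        if t_ed is None:
            t_ed = beat.t0
    else:
        t_ed = beat.t0
    beat.events = {"t_es": t_es, "t_ed": t_ed}
    return t_es, t_ed


def pv_loop_area(p_series: np.ndarray, v_series: np.ndarray) -> float:
    """Absolute shoelace area of a closed pressure-volume loop, in joules.

    The first point is implicitly appended as the last, so an open beat
    path is closed by a chord.  Orientation-invariant.
    """
    p = np.asarray(p_series, dtype=float)
    v = np.asarray(v_series, dtype=float)
    if p.shape != v.shape or p.ndim != 1:
        raise ValueError("P and V series must be 1-D and equally long")
    if p.size < 3:
        raise ValueError("a loop needs at least 3 points")
    cross = v * np.roll(p, -1) - np.roll(v, -1) * p
    return abs(0.5 * cross.sum()) * MMHG_ML_TO_J


def beat_energetics(
    v_lved: float,
    v_lves: float,
    p_lved: float,
    p_lves: float,
    sw_j: float,
    p_lv_mean: float,
    p_sas_syst: float,
    rr: float,
    v_unstressed: float = LV_UNSTRESSED_ML,
) -> dict[str, float]:
    """Scalar per-beat indices from located es/ed values.

    SV = V_lved - V_lves;  EF = SV/V_lved x 100;
    PE = P_lves (V_lves - V_un)/2 - P_lved (V_lved - V_un)/4  (in J);
    PVA = PE + SW;  efficiency = SW/PVA x 100;
    CO = SV x 60/RR (L/min);  RPP = P_sas,syst x 60/RR (mmHg/min);
    TTI = beat-mean P_lv x RR (mmHg.s), TTI/min = TTI x 60/RR.
    """
    if v_lved <= 0:
        raise ValueError("V_lved must be positive")
    hr_inst = 60.0 / rr
    sv = v_lved - v_lves
    ef = sv / v_lved * 100.0
    pe = (
        p_lves * (v_lves - v_unstressed) / 2.0
        - p_lved * (v_lved - v_unstressed) / 4.0
    ) * MMHG_ML_TO_J
    pva = pe + sw_j
    out = {
        "sv": sv,
        "ef": ef,
        "sw": sw_j,
        "pe": pe,
        "pva": pva,
        "co": sv * hr_inst / 1000.0,
        "rpp": p_sas_syst * hr_inst,
        "tti": p_lv_mean * rr,
        "tti_min": p_lv_mean * 60.0,
        "pva_min": pva * hr_inst,
        "sw_pva": np.nan if pva == 0 else sw_j / pva * 100.0,
    }
    return out


def _interp(t: np.ndarray, x: np.ndarray, ti: float) -> float:
    return float(np.interp(ti, t, x))


def summarize(trace: BeatTrace) -> pd.DataFrame:
    """Per-beat summary table (one row per analyzed beat).

    Non-ejecting beats (aortic valve never opened) get ``ejecting=False``
    and NaN ejection indices; they are excluded from EF/SW-family
    statistics by :func:`aggregate` but remain counted.
    """
    beats = segment_beats(trace)
    rows = []
    for beat in beats:
        row: dict[str, float] = {
            "rr": beat.rr,
            "hr_inst": 60.0 / beat.rr,
            "p_la": beat.p_la.mean(),
            "p_lv": beat.p_lv.mean(),
            "p_sas": beat.p_sas.mean(),
            "p_pas": beat.p_pas.mean(),
            "p_pvn": beat.p_pvn.mean(),
            "v_la": beat.v_la.mean(),
            "v_lv": beat.v_lv.mean(),
            "p_lv_max": beat.p_lv.max(),
            "p_lv_min": beat.p_lv.min(),
            "p_sas_syst": beat.p_sas.max(),
            "p_sas_dias": beat.p_sas.min(),
            "p_pas_syst": beat.p_pas.max(),
            "p_pas_dias": beat.p_pas.min(),
        }
        try:
            t_es, t_ed = locate_es_ed(beat)
            ejecting = True
        except ValueError:
            ejecting = False
        row["ejecting"] = ejecting
        if ejecting:
            row["t_es"] = t_es
            row["t_ed"] = t_ed
            row["p_laes"] = _interp(beat.t, beat.p_la, t_es)
            row["p_laed"] = _interp(beat.t, beat.p_la, t_ed)
            row["v_laes"] = _interp(beat.t, beat.v_la, t_es)
            row["v_laed"] = _interp(beat.t, beat.v_la, t_ed)
            row["p_lves"] = _interp(beat.t, beat.p_lv, t_es)
            row["p_lved"] = _interp(beat.t, beat.p_lv, t_ed)
            row["v_lves"] = _interp(beat.t, beat.v_lv, t_es)
            row["v_lved"] = _interp(beat.t, beat.v_lv, t_ed)
            sw = pv_loop_area(beat.p_lv, beat.v_lv)
            row.update(
                beat_energetics(
                    v_lved=row["v_lved"],
                    v_lves=row["v_lves"],
                    p_lved=row["p_lved"],
                    p_lves=row["p_lves"],
                    sw_j=sw,
                    p_lv_mean=row["p_lv"],
                    p_sas_syst=row["p_sas_syst"],
                    rr=beat.rr,
                )
            )
        rows.append(row)
    return pd.DataFrame(rows)


#: Columns meaningless for (and therefore NaN on) non-ejecting beats.
_EJECTION_COLS = [
    "sv", "ef", "sw", "pe", "pva", "co", "rpp", "tti", "tti_min",
    "pva_min", "sw_pva", "p_laes", "p_laed", "v_laes", "v_laed",
    "p_lves", "p_lved", "v_lves", "v_lved", "t_es", "t_ed",
]


def aggregate(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of every index over the analyzed beats.

    Returns a frame indexed by parameter with columns ``mean``, ``sd`` and
    ``n``; non-ejecting beats contribute only to the indices defined for
    them.  Raises on fewer than 2 beats.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 beats to aggregate")
    num = summaries.drop(columns=["ejecting"], errors="ignore").select_dtypes("number")
    out = pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "n": num.count().astype(int),
        }
    )
    out.attrs["n_beats"] = len(summaries)
    if "ejecting" in summaries:
        out.attrs["n_non_ejecting"] = int((~summaries["ejecting"]).sum())
    return out


def write_summary_csv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index=False, float_format="%.6g")
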