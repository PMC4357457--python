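"""Closed-loop lumped-parameter circulation driven by an RR sequence.

The model couples four heart chambers (time-varying elastance ventricles,
passive atria) with systemic and pulmonary vascular beds in a single closed
hydraulic loop.  For every compartment the governing equations are

* mass conservation  dV/dt = Q_in - Q_out,
* a linear state equation  P = E(t) (V - V_un)  for chambers and
  P = (V - V_un)/C  for vessels,
* an equation of motion  L dQ/dt = dP - R Q  on inertial branches
  (the four valves, which additionally rectify: no regurgitant flow).

Volumes are the primary states, so total blood volume is a linear invariant
of the vector field and is conserved by the integrator up to round-off.

Integration proceeds beat by beat: the ventricular activation clock resets
at every RR onset, the systolic duration contracting with rate as
T_sys = k*sqrt(RR).  The stiff portions (valve openings, fast ejection
transients) are handled by an adaptive multistep solver (LSODA by default,
switching to BDF when stiff).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ModelParameters, PARAM_INDEX

__all__ = [
    "SolverOptions",
    "BeatTrace",
    "ventricular_activation",
    "systolic_duration",
    "chamber_pressure",
    "valve_flow",
    "derivatives",
    "build_initial_state",
    "simulate",
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_npz",
    "read_trace_npz",
    "STATE_NAMES",
]

STATE_NAMES = [
    "v_la", "v_lv", "v_ra", "v_rv",
    "v_sas", "v_svn", "v_pas", "v_pvn",
    "q_mi", "q_ao", "q_ti", "q_po",
]

# Parameter-array indices (compile-time constants for the jitted RHS).
_LV_EMAX = PARAM_INDEX["lv_emax"]
_LV_EMIN = PARAM_INDEX["lv_emin"]
_LV_V0 = PARAM_INDEX["lv_v0"]
_LA_E = PARAM_INDEX["la_e"]
_LA_V0 = PARAM_INDEX["la_v0"]
_RV_EMAX = PARAM_INDEX["rv_emax"]
_RV_EMIN = PARAM_INDEX["rv_emin"]
_RV_V0 = PARAM_INDEX["rv_v0"]
_RA_E = PARAM_INDEX["ra_e"]
_RA_V0 = PARAM_INDEX["ra_v0"]
_MI_R = PARAM_INDEX["mi_r"]
_MI_L = PARAM_INDEX["mi_l"]
_AO_R = PARAM_INDEX["ao_r"]
_AO_L = PARAM_INDEX["ao_l"]
_TI_R = PARAM_INDEX["ti_r"]
_TI_L = PARAM_INDEX["ti_l"]
_PO_R = PARAM_INDEX["po_r"]
_PO_L = PARAM_INDEX["po_l"]
_SA_C = PARAM_INDEX["sa_c"]
_SA_V0 = PARAM_INDEX["sa_v0"]
_SV_C = PARAM_INDEX["sv_c"]
_SV_V0 = PARAM_INDEX["sv_v0"]
_PA_C = PARAM_INDEX["pa_c"]
_PA_V0 = PARAM_INDEX["pa_v0"]
_PV_C = PARAM_INDEX["pv_c"]
_PV_V0 = PARAM_INDEX["pv_v0"]
_ACT_PEAK = PARAM_INDEX["act_peak_frac"]
_R_SYS = PARAM_INDEX["r_sys"]
_R_VEN = PARAM_INDEX["r_ven"]
_R_PUL = PARAM_INDEX["r_pul"]
_R_PV = PARAM_INDEX["r_pv"]

# Time constant (s) relaxing a (numerically) negative valve-flow state back
# to zero while the valve is shut; sets the fastest mode of the system.
_VALVE_RELAX = 2e-3


def _rhs_py(t, y, p, tsys):
    if 0.0 <= t < tsys:
        tp = p[_ACT_PEAK] * tsys
        if t < tp:
            s = np.sin(0.5 * np.pi * t / tp)
        else:
            s = np.cos(0.5 * np.pi * (t - tp) / (tsys - tp))
        act = s * s
    else:
        act = 0.0

    p_la = p[_LA_E] * (y[0] - p[_LA_V0])
    e_lv = p[_LV_EMIN] + act * (p[_LV_EMAX] - p[_LV_EMIN])
    p_lv = e_lv * (y[1] - p[_LV_V0])
    p_ra = p[_RA_E] * (y[2] - p[_RA_V0])
    e_rv = p[_RV_EMIN] + act * (p[_RV_EMAX] - p[_RV_EMIN])
    p_rv = e_rv * (y[3] - p[_RV_V0])
    p_sa = (y[4] - p[_SA_V0]) / p[_SA_C]
    p_sv = (y[5] - p[_SV_V0]) / p[_SV_C]
    p_pa = (y[6] - p[_PA_V0]) / p[_PA_C]
    p_pv = (y[7] - p[_PV_V0]) / p[_PV_C]

    dy = np.empty(12)

    # Valve branches: rectified inertial flow.
    q_mi, q_ao, q_ti, q_po = y[8], y[9], y[10], y[11]
    dp_mi = p_la - p_lv
    dp_ao = p_lv - p_sa
    dp_ti = p_ra - p_rv
    dp_po = p_rv - p_pa
    # Valve open while flow persists or the gradient is favourable; a shut
    # valve's (slightly negative) flow state relaxes back to zero.
    dy[8] = (dp_mi - p[_MI_R] * q_mi) / p[_MI_L] if (q_mi > 0.0 or dp_mi > 0.0) else -q_mi / _VALVE_RELAX
    dy[9] = (dp_ao - p[_AO_R] * q_ao) / p[_AO_L] if (q_ao > 0.0 or dp_ao > 0.0) else -q_ao / _VALVE_RELAX
    dy[10] = (dp_ti - p[_TI_R] * q_ti) / p[_TI_L] if (q_ti > 0.0 or dp_ti > 0.0) else -q_ti / _VALVE_RELAX
    dy[11] = (dp_po - p[_PO_R] * q_po) / p[_PO_L] if (q_po > 0.0 or dp_po > 0.0) else -q_po / _VALVE_RELAX

    q_mi_e = q_mi if q_mi > 0.0 else 0.0
    q_ao_e = q_ao if q_ao > 0.0 else 0.0
    q_ti_e = q_ti if q_ti > 0.0 else 0.0
    q_po_e = q_po if q_po > 0.0 else 0.0

    # Inter-compartment (non-valvular) flows: purely resistive.
    q_sys = (p_sa - p_sv) / p[_R_SYS]
    q_ven = (p_sv - p_ra) / p[_R_VEN]
    q_pul = (p_pa - p_pv) / p[_R_PUL]
    q_pvn = (p_pv - p_la) / p[_R_PV]

    dy[0] = q_pvn - q_mi_e
    dy[1] = q_mi_e - q_ao_e
    dy[2] = q_ven - q_ti_e
    dy[3] = q_ti_e - q_po_e
    dy[4] = q_ao_e - q_sys
    dy[5] = q_sys - q_ven
    dy[6] = q_po_e - q_pul
    dy[7] = q_pul - q_pvn
    return dy


def _rk4_beat_py(y0, p, rr, tsys, ns, nsub):
    """Integrate one beat with classical RK4 at fixed step rr/(ns*nsub),
    returning samples at the uniform ns-point grid and the state at t=rr."""
    out = np.empty((ns, 12))
    y = y0.copy()
    dt = rr / (ns * nsub)
    h2 = dt / 2.0
    h6 = dt / 6.0
    t = 0.0
    for i in range(ns):
        out[i] = y
        for _ in range(nsub):
            k1 = _rhs(t, y, p, tsys)
            k2 = _rhs(t + h2, y + h2 * k1, p, tsys)
            k3 = _rhs(t + h2, y + h2 * k2, p, tsys)
            k4 = _rhs(t + dt, y + dt * k3, p, tsys)
            y = y + h6 * (k1 + 2.0 * (k2 + k3) + k4)
            t += dt
    return out, y


try:  # optional acceleration; the pure-Python path is the reference
    from numba import njit

    _rhs = njit(cache=False, fastmath=False)(_rhs_py)
    _rk4_beat = njit(cache=False, fastmath=False)(_rk4_beat_py)
    _rk4_beat(np.ones(12), np.ones(len(PARAM_INDEX)), 0.8, 0.3, 4, 2)  # warm
except Exception:  # pragma: no cover - numba is an optional extra
    _rhs = _rhs_py
    _rk4_beat = _rk4_beat_py


def systolic_duration(rr: float, k: float) -> float:
    """Systolic duration T_sys = k*sqrt(RR), capped at 85% of the beat.

    The square-root law shortens systole less than diastole as the beat
    contracts, so the systolic *fraction* grows at fast rates — the
    mechanism behind diastolic-time starvation at high heart rate.
    """
    return min(k * np.sqrt(rr), 0.85 * rr)


def activation_waveform(
    t_in_systole: np.ndarray, tsys: float, peak_frac: float = 0.5
) -> np.ndarray:
    """Smooth unimodal activation: squared-sine rise to 1 at
    ``peak_frac * tsys``, squared-cosine relaxation back to 0 at ``tsys``;
    zero outside [0, tsys)."""
    t = np.asarray(t_in_systole, dtype=float)
    tp = peak_frac * tsys
    rise = np.sin(0.5 * np.pi * np.clip(t, 0.0, tp) / tp) ** 2
    fall = np.cos(0.5 * np.pi * np.clip(t - tp, 0.0, tsys - tp) / (tsys - tp)) ** 2
    a = np.where(t < tp, rise, fall)
    return np.where((t >= 0) & (t < tsys), a, 0.0)


def ventricular_activation(
    t_in_beat: float, rr: float, k: float = 0.44, peak_frac: float = 0.5
) -> float:
    """Normalised ventricular activation (0..1) at time ``t_in_beat`` of a
    beat of length ``rr``; systole spans ``T_sys = k*sqrt(rr)``, the rest of
    the beat is fully diastolic."""
    if not 0 <= t_in_beat < rr:
        raise ValueError(f"t_in_beat={t_in_beat} outside [0, rr={rr})")
    tsys = systolic_duration(rr, k)
    return float(activation_waveform(t_in_beat, tsys, peak_frac))


def chamber_pressure(
    volume: float,
    activation: float,
    e_min: float,
    e_max: float,
    v_unstressed: float,
    passive: bool = False,
) -> float:
    """Linear state equation P = [E_min + a (E_max - E_min)] (V - V_un).

    ``passive=True`` forces activation to zero — the atrial mode mimicking
    the loss of atrial kick in fibrillation.
    """
    if volume < 0:
        raise ValueError("volume must be >= 0")
    a = 0.0 if passive else activation
    elastance = e_min + a * (e_max - e_min)
    return elastance * (volume - v_unstressed)


def valve_flow(p_up: float, p_down: float, r_open: float) -> float:
    """Quasi-static diode valve: Q = (P_up - P_down)/R when forward-biased,
    zero otherwise (never regurgitant)."""
    if not (np.isfinite(p_up) and np.isfinite(p_down)):
        raise ValueError("pressures must be finite")
    dp = p_up - p_down
    return dp / r_open if dp > 0 else 0.0


def derivatives(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    current_rr: float,
    t_beat_start: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full state vector (see ``STATE_NAMES``).

    ``t`` is absolute; the activation clock runs from ``t_beat_start``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (12,):
        raise ValueError("state must have 12 components")
    if not np.all(np.isfinite(state)):
        bad = [n for n, v in zip(STATE_NAMES, state) if not np.isfinite(v)]
        raise ValueError(f"non-finite state component(s): {bad}")
    tsys = systolic_duration(current_rr, params.tsys_k)
    return np.asarray(_rhs(t - t_beat_start, state, params.as_array(), tsys))


@dataclass
class SolverOptions:
    """Integration controls for :func:`simulate`.

    The default method is a compiled fixed-step RK4 ("rk4") whose step
    ``dt`` resolves the fastest valve mode; any scipy ``solve_ivp`` method
    name ("RK45", "LSODA", "BDF", ...) selects the adaptive path instead
    (with ``rtol``/``atol`` control), which serves as an independent
    integration route for cross-checks.
    """

    method: str = "rk4"
    dt: float = 2e-4
    rtol: float = 1e-6
    atol: float = 1e-8
    samples_per_beat: int = 200
    warmup_beats: int = 20
    max_step: float = 0.02
    volume_drift_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.dt <= 0:
            raise ValueError("solver tolerances and dt must be positive")
        if self.samples_per_beat < 50:
            raise ValueError("samples_per_beat must be >= 50")


# Columns stored in a BeatTrace (beyond time and raw state).
_PRESSURE_COLS = ["p_la", "p_lv", "p_ra", "p_rv", "p_sas", "p_svn", "p_pas", "p_pvn"]
_FLOW_COLS = ["q_mi", "q_ao", "q_ti", "q_po"]


@dataclass
class BeatTrace:
    """Dense simulated time series with beat-onset bookkeeping.

    ``beat_start`` holds the sample index of each analyzed beat's onset
    (activation-clock reset); ``rr`` the corresponding interval drawn from
    the RR sequence.  Warm-up beats are excluded from the stored trace.
    """

    t: np.ndarray
    y: np.ndarray  # (n_samples, 12) raw state
    beat_start: np.ndarray  # (n_beats,) sample indices
    rr: np.ndarray  # (n_beats,)
    params: ModelParameters
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.rr)

    def _elastances(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        act = np.zeros_like(self.t)
        bounds = np.r_[self.beat_start, len(self.t)]
        for i in range(self.n_beats):
            sl = slice(bounds[i], bounds[i + 1])
            tl = self.t[sl] - self.t[self.beat_start[i]]
            tsys = systolic_duration(self.rr[i], p.tsys_k)
            act[sl] = activation_waveform(tl, tsys, p.act_peak_frac)
        e_lv = p.lv_emin + act * (p.lv_emax - p.lv_emin)
        e_rv = p.rv_emin + act * (p.rv_emax - p.rv_emin)
        return e_lv, e_rv

    @property
    def pressures(self) -> dict[str, np.ndarray]:
        """Chamber and vessel pressures (mmHg) reconstructed from state."""
        p, y = self.params, self.y
        e_lv, e_rv = self._elastances()
        return {
            "p_la": p.la_e * (y[:, 0] - p.la_v0),
            "p_lv": e_lv * (y[:, 1] - p.lv_v0),
            "p_ra": p.ra_e * (y[:, 2] - p.ra_v0),
            "p_rv": e_rv * (y[:, 3] - p.rv_v0),
            "p_sas": (y[:, 4] - p.sa_v0) / p.sa_c,
            "p_svn": (y[:, 5] - p.sv_v0) / p.sv_c,
            "p_pas": (y[:, 6] - p.pa_v0) / p.pa_c,
            "p_pvn": (y[:, 7] - p.pv_v0) / p.pv_c,
        }

    @property
    def volumes(self) -> dict[str, np.ndarray]:
        return {
            "v_la": self.y[:, 0],
            "v_lv": self.y[:, 1],
            "v_ra": self.y[:, 2],
            "v_rv": self.y[:, 3],
        }

    @property
    def flows(self) -> dict[str, np.ndarray]:
        """Rectified valve flows (mL/s); always >= 0."""
        return {
            name: np.maximum(self.y[:, 8 + i], 0.0)
            for i, name in enumerate(_FLOW_COLS)
        }

    @property
    def valve_open(self) -> dict[str, np.ndarray]:
        return {name: q > 1e-9 for name, q in self.flows.items()}

    @property
    def total_volume(self) -> np.ndarray:
        return self.y[:, :8].sum(axis=1)

    @property
    def volume_drift(self) -> float:
        """Max relative deviation of total blood volume from its initial
        value — the closed-loop conservation metric."""
        v = self.total_volume
        return float(np.max(np.abs(v - v[0])) / v[0])


def build_initial_state(params: ModelParameters) -> np.ndarray:
    """A physiologically reasonable diastolic initial condition.

    Chambers start near typical diastolic volumes and the arterial and
    pulmonary compartments near their working pressures; the systemic veins
    absorb the remaining blood volume (they are the capacitance reservoir),
    so the state sums exactly to ``params.total_volume``.
    """
    p = params
    y = np.zeros(12)
    y[0] = p.la_v0 + 9.0 / p.la_e  # left atrium ~9 mmHg
    y[1] = p.lv_v0 + 10.0 / p.lv_emin  # LV at ~10 mmHg passive
    y[2] = p.ra_v0 + 4.0 / p.ra_e
    y[3] = p.rv_v0 + 4.0 / p.rv_emin
    y[4] = p.sa_v0 + 80.0 * p.sa_c
    y[6] = p.pa_v0 + 15.0 * p.pa_c
    y[7] = p.pv_v0 + 10.0 * p.pv_c
    used = y[:8].sum()
    y[5] = p.total_volume - used
    if y[5] <= p.sv_v0 * 0.5:
        raise ValueError(
            "total_volume too small to fill the venous reservoir"
        )
    return y


def simulate(
    rr_seq,
    params: ModelParameters | None = None,
    init: np.ndarray | None = None,
    solver: SolverOptions | None = None,
) -> BeatTrace:
    """Integrate the closed loop over an RR sequence, beat by beat.

    The first ``solver.warmup_beats`` beats are simulated with the *mean*
    RR of the sequence to flush the initial condition, then discarded; the
    stored trace covers exactly the beats of ``rr_seq``.

    Raises
    ------
    RuntimeError
        On solver failure (naming the beat index) or if total blood volume
        drifts beyond ``solver.volume_drift_tol`` (closed-loop violation).
    """
    from .parameters import default_params

    if params is None:
        params = default_params()
    if solver is None:
        solver = SolverOptions()
    intervals = np.asarray(
        getattr(rr_seq, "intervals", rr_seq), dtype=float
    )
    if intervals.ndim != 1 or intervals.size == 0:
        raise ValueError("rr_seq must contain at least one interval")
    if np.any(intervals <= 0):
        raise ValueError("RR intervals must be positive")

    p_arr = params.as_array()
    y = np.asarray(init, dtype=float) if init is not None else build_initial_state(params)
    if y.shape != (12,):
        raise ValueError("init state must have 12 components")

    warm = np.full(solver.warmup_beats, intervals.mean())
    all_rr = np.r_[warm, intervals]
    ns = solver.samples_per_beat
    n_an = intervals.size

    t_list: list[np.ndarray] = []
    y_list: list[np.ndarray] = []
    beat_start = np.empty(n_an, dtype=np.int64)
    t_abs = 0.0
    kept = 0
    n_samples = 0
    use_rk4 = solver.method.lower() == "rk4"
    for b, rr in enumerate(all_rr):
        tsys = systolic_duration(rr, params.tsys_k)
        grid = np.linspace(0.0, rr, ns + 1)
        if use_rk4:
            nsub = max(1, int(np.ceil(rr / (ns * solver.dt))))
            samples, y = _rk4_beat(y, p_arr, rr, tsys, ns, nsub)
        else:
            sol = solve_ivp(
                _rhs,
                (0.0, rr),
                y,
                method=solver.method,
                t_eval=grid,
                args=(p_arr, tsys),
                rtol=solver.rtol,
                atol=solver.atol,
                max_step=solver.max_step,
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE solver failed at beat {b}: {sol.message}"
                )
            samples = sol.y[:, :-1].T
            y = sol.y[:, -1].copy()
        if not np.all(np.isfinite(y)):
            bad = [n for n, v in zip(STATE_NAMES, y) if not np.isfinite(v)]
            raise RuntimeError(
                f"non-finite state after beat {b}: {bad}"
            )
        if b >= solver.warmup_beats:
            t_list.append(t_abs + grid[:-1])
            y_list.append(samples)
            beat_start[kept] = n_samples
            n_samples += ns
            kept += 1
            t_abs += rr

    trace = BeatTrace(
        t=np.concatenate(t_list),
        y=np.vstack(y_list),
        beat_start=beat_start,
        rr=intervals.copy(),
        params=params,
        meta={
            "solver": solver.method,
            "rtol": solver.rtol,
            "atol": solver.atol,
            "samples_per_beat": ns,
            "warmup_beats": solver.warmup_beats,
            "params_sha1": hashlib.sha1(p_arr.tobytes()).hexdigest(),
        },
    )
    if trace.volume_drift > solver.volume_drift_tol:
        raise RuntimeError(
            f"blood volume drifted by {trace.volume_drift:.3e} relative "
            f"(tolerance {solver.volume_drift_tol:.1e}); closed loop violated"
        )
    return trace


def _trace_frame(trace: BeatTrace):
    import pandas as pd

    d = {"t": trace.t}
    d.update(trace.pressures)
    d.update(trace.volumes)
    d.update(trace.flows)
    for name, flag in trace.valve_open.items():
        d[name.replace("q_", "open_")] = flag.astype(int)
    beat = np.zeros(len(trace.t), dtype=int)
    bounds = np.r_[trace.beat_start, len(trace.t)]
    for i in range(trace.n_beats):
        beat[bounds[i] : bounds[i + 1]] = i
    d["beat"] = beat
    return pd.DataFrame(d)


def write_trace_csv(trace: BeatTrace, path) -> None:
    """One row per sample: time, pressures, volumes, valve flows and flags,
    and the owning beat index."""
    _trace_frame(trace).to_csv(path, index=False, float_format="%.6g")


def write_trace_npz(trace: BeatTrace, path) -> None:
    """Compact binary trace (for long runs where CSV is impractical)."""
    np.savez_compressed(
        path,
        t=trace.t,
        y=trace.y,
        beat_start=trace.beat_start,
        rr=trace.rr,
        params=trace.params.as_array(),
    )


def read_trace_npz(path, params: ModelParameters | None = None) -> BeatTrace:
    from .parameters import default_params

    with np.load(path) as z:
        if params is None:
            params = default_params()
            if not np.allclose(params.as_array(), z["params"]):
                raise ValueError(
                    "trace was produced with a non-default parameter set; "
                    "pass params explicitly"
                )
        return BeatTrace(
            t=z["t"], y=z["y"], beat_start=z["beat_start"], rr=z["rr"],
            params=params,
        )


def read_trace_csv(path, params: ModelParameters, rr: np.ndarray) -> "BeatTrace":
    """Rebuild a BeatTrace from the CSV writer's output.

    The CSV stores derived quantities; the raw state is reassembled from
    volumes, flows, and vessel pressures (exact up to print precision).
    """
    import pandas as pd

    df = pd.read_csv(path)
    p = params
    y = np.column_stack([
        df["v_la"], df["v_lv"], df["v_ra"], df["v_rv"],
        df["p_sas"] * p.sa_c + p.sa_v0,
        df["p_svn"] * p.sv_c + p.sv_v0,
        df["p_pas"] * p.pa_c + p.pa_v0,
        df["p_pvn"] * p.pv_c + p.pv_v0,
        df["q_mi"], df["q_ao"], df["q_ti"], df["q_po"],
    ])
    beat = df["beat"].to_numpy()
    starts = np.flatnonzero(np.r_[True, np.diff(beat) != 0])
    return BeatTrace(
        t=df["t"].to_numpy(), y=y, beat_start=starts,
        rr=np.asarray(rr, dtype=float), params=params,
    )
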