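"""Analytic test fixtures: beats and summary streams with known answers.

These generators exist to pin the arithmetic of the index pipeline without
running the circulation model: every fixture carries its exact expected
outputs (loop area, stroke volume, planted event times, planted moments).
They make no attempt at physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import MMHG_ML_TO_J, Beat

__all__ = ["AnalyticBeatSpec", "make_analytic_beat", "make_summary_stream"]


@dataclass(frozen=True)
class AnalyticBeatSpec:
    """Recipe for an analytic pressure-volume loop traced over one beat.

    ``shape`` is "rectangle" or "ellipse"; the loop spans ``p_range`` x
    ``v_range`` (a full-axis bounding box for the ellipse).  Valve events
    are planted at ``t_es``/``t_ed`` (s inside [0, rr)).
    """

    shape: str = "rectangle"
    p_range: tuple[float, float] = (10.0, 100.0)
    v_range: tuple[float, float] = (50.0, 130.0)
    rr: float = 1.2
    t_es: float = 0.30
    t_ed: float = 0.95
    samples: int = 500

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown loop shape {self.shape!r}")
        if self.p_range[1] <= self.p_range[0] or self.v_range[1] <= self.v_range[0]:
            raise ValueError("degenerate pressure or volume range")
        if not (0 <= self.t_es < self.rr and 0 <= self.t_ed < self.rr):
            raise ValueError("planted events must lie inside [0, rr)")
        if self.samples < 8:
            raise ValueError("need at least 8 samples")


def make_analytic_beat(spec: AnalyticBeatSpec) -> tuple[Beat, dict[str, float]]:
    """Build a :class:`Beat` tracing the requested loop, plus exact values.

    The returned dict holds ``sw_exact`` (J), ``sv_exact`` (mL) and
    ``ef_exact`` (%) implied by the loop geometry.  Valve-closure events are
    planted by shaping the raw flow signals to cross zero downward exactly
    at ``t_es`` (aortic) and ``t_ed`` (mitral).
    """
    p0, p1 = spec.p_range
    v0, v1 = spec.v_range
    n = spec.samples
    t = np.linspace(0.0, spec.rr, n, endpoint=False)
    phase = 2 * np.pi * np.arange(n) / n
    if spec.shape == "rectangle":
        # counter-clockwise rectangle traced in 4 equal legs
        q = n // 4
        v = np.empty(n)
        p = np.empty(n)
        legs = np.split(np.arange(n), [q, 2 * q, 3 * q])
        f = [np.linspace(0, 1, len(leg), endpoint=False) for leg in legs]
        v[legs[0]] = v0 + (v1 - v0) * f[0]; p[legs[0]] = p0
        v[legs[1]] = v1; p[legs[1]] = p0 + (p1 - p0) * f[1]
        v[legs[2]] = v1 - (v1 - v0) * f[2]; p[legs[2]] = p1
        v[legs[3]] = v0; p[legs[3]] = p1 - (p1 - p0) * f[3]
        area = (p1 - p0) * (v1 - v0)
    else:
        a = (v1 - v0) / 2.0  # volume semi-axis
        b = (p1 - p0) / 2.0  # pressure semi-axis
        v = (v0 + v1) / 2.0 + a * np.cos(phase)
        p = (p0 + p1) / 2.0 + b * np.sin(phase)
        area = np.pi * a * b
    sv = v1 - v0
    exact = {
        "sw_exact": area * MMHG_ML_TO_J,
        "sv_exact": sv,
        "ef_exact": sv / v1 * 100.0,
    }
    # plant flow signals whose only downward zero crossings sit at the
    # requested event times
    q_ao = -np.sin(np.pi * (t - spec.t_es) / spec.rr) * 100.0
    q_mi = -np.sin(np.pi * (t - spec.t_ed) / spec.rr) * 100.0
    beat = Beat(
        t=t,
        rr=spec.rr,
        p_la=np.full(n, 8.0),
        p_lv=p,
        p_sas=np.full(n, 90.0),
        p_pas=np.full(n, 18.0),
        p_pvn=np.full(n, 10.0),
        v_la=np.full(n, 60.0),
        v_lv=v,
        q_mi_raw=q_mi,
        q_ao_raw=q_ao,
    )
    return beat, exact


def make_summary_stream(
    n: int,
    index_means: dict[str, float],
    index_sds: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gaussian per-beat summaries with planted moments.

    Useful for exercising aggregation and stationarity checks against known
    truth; columns not given an SD are held constant at their mean.
    """
    if n < 2:
        raise ValueError("need n >= 2 beats")
    index_sds = index_sds or {}
    bad = {k: s for k, s in index_sds.items() if s < 0}
    if bad:
        raise ValueError(f"negative SDs: {bad}")
    rng = np.random.default_rng(seed)
    data = {}
    for name, mu in index_means.items():
        sd = index_sds.get(name, 0.0)
        data[name] = rng.normal(mu, sd, n) if sd > 0 else np.full(n, float(mu))
    df = pd.DataFrame(data)
    df["ejecting"] = True
    return df
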