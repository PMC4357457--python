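"""The heart-rate sweep experiment: AF at 50-130 bpm, fixed cv.

Runs the full pipeline (RR sampling -> closed-loop simulation -> per-beat
indices -> aggregation) at each requested mean heart rate, assembles the
per-HR index table (mean +/- SD of every reported parameter), computes the
percent variation of each parameter relative to the lowest-rate reference
column, and flags "relevant" parameters whose maximum variation exceeds
15% in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .rr import AF_CV, DEFAULT_RR_MIN, DEFAULT_TAU_FRACTION, exgauss_from_moments, exgauss_pdf, sample_rr
from .model import SolverOptions, simulate
from .indices import aggregate, summarize, write_summary_csv
from .parameters import ModelParameters, default_params

__all__ = [
    "SweepConfig",
    "SweepResult",
    "TABLE_ROWS",
    "run_sweep",
    "percent_variation",
    "stationarity_check",
    "render_outputs",
]

#: Display label -> per-beat summary column, in reporting order.
TABLE_ROWS: dict[str, str] = {
    "P_la [mmHg]": "p_la",
    "P_laes [mmHg]": "p_laes",
    "P_laed [mmHg]": "p_laed",
    "V_la [ml]": "v_la",
    "V_laes [ml]": "v_laes",
    "V_laed [ml]": "v_laed",
    "P_lv [mmHg]": "p_lv",
    "P_lves [mmHg]": "p_lves",
    "P_lved [mmHg]": "p_lved",
    "P_lv,max [mmHg]": "p_lv_max",
    "P_lv,min [mmHg]": "p_lv_min",
    "V_lv [ml]": "v_lv",
    "V_lves [ml]": "v_lves",
    "V_lved [ml]": "v_lved",
    "P_sas [mmHg]": "p_sas",
    "P_sas,dias [mmHg]": "p_sas_dias",
    "P_sas,syst [mmHg]": "p_sas_syst",
    "P_pas [mmHg]": "p_pas",
    "P_pas,dias [mmHg]": "p_pas_dias",
    "P_pas,syst [mmHg]": "p_pas_syst",
    "P_pvn [mmHg]": "p_pvn",
    "SV [ml]": "sv",
    "EF [%]": "ef",
    "SW [J]": "sw",
    "CO [l/min]": "co",
    "RPP [mmHg/min]": "rpp",
    "TTI/min [mmHg s/min]": "tti_min",
    "PVA/min [J/min]": "pva_min",
    "SW/PVA [%]": "sw_pva",
}

#: Magnitude of percent variation above which a parameter is "relevant".
RELEVANCE_THRESHOLD = 15.0


@dataclass
class SweepConfig:
    """Configuration of one sweep experiment."""

    hr_list: tuple[float, ...] = (50.0, 70.0, 90.0, 110.0, 130.0)
    beats_per_hr: int = 5000
    cv: float = AF_CV
    tau_fraction: float = DEFAULT_TAU_FRACTION
    rr_min: float = DEFAULT_RR_MIN
    seed: int = 42
    params: ModelParameters | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if len(self.hr_list) == 0 or any(h <= 0 for h in self.hr_list):
            raise ValueError("hr_list must be nonempty and positive")
        if self.beats_per_hr < 100:
            raise ValueError("beats_per_hr must be >= 100")

    def hr_seeds(self) -> dict[float, int]:
        """Deterministic, jointly reproducible per-HR seeds derived from the
        master seed (independent streams per column)."""
        state = np.random.SeedSequence(self.seed).generate_state(len(self.hr_list))
        return {hr: int(s % (2**31)) for hr, s in zip(self.hr_list, state)}


@dataclass
class SweepResult:
    table: pd.DataFrame  # index table: mean/sd per parameter x HR + variation
    summaries: dict[float, pd.DataFrame]  # per-HR per-beat summaries
    manifest: dict
    repr_traces: dict[float, pd.DataFrame] = field(default_factory=dict)


def percent_variation(value_ref: float, value_cmp: float) -> float:
    """100 x (cmp - ref)/ref; raises on a zero reference."""
    if value_ref == 0:
        raise ValueError("percent variation undefined for zero reference")
    return 100.0 * (value_cmp - value_ref) / value_ref


def _index_table(agg_by_hr: dict[float, pd.DataFrame]) -> pd.DataFrame:
    hrs = list(agg_by_hr)
    ref = hrs[0]
    rows = []
    for label, col in TABLE_ROWS.items():
        means = {hr: agg_by_hr[hr]["mean"].get(col, np.nan) for hr in hrs}
        sds = {hr: agg_by_hr[hr]["sd"].get(col, np.nan) for hr in hrs}
        # maximum % variation vs the reference column
        devs = [percent_variation(means[ref], means[hr]) for hr in hrs[1:]]
        max_var = (
            devs[int(np.argmax(np.abs(devs)))] if devs else 0.0
        )
        row = {"parameter": label}
        for hr in hrs:
            row[f"mean_{hr:g}"] = means[hr]
            row[f"sd_{hr:g}"] = sds[hr]
        row["max_variation_pct"] = round(max_var)
        row["relevant"] = abs(max_var) > RELEVANCE_THRESHOLD
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def run_sweep(config: SweepConfig) -> SweepResult:
    """Execute the sweep serially; per-HR columns use independent seeded
    streams, so results do not depend on execution order."""
    params = config.params if config.params is not None else default_params()
    seeds = config.hr_seeds()
    aggs: dict[float, pd.DataFrame] = {}
    summaries: dict[float, pd.DataFrame] = {}
    repr_traces: dict[float, pd.DataFrame] = {}
    non_ejecting: dict[float, int] = {}
    for hr in config.hr_list:
        seq = sample_rr(
            config.beats_per_hr,
            hr,
            cv=config.cv,
            tau_fraction=config.tau_fraction,
            rr_min=config.rr_min,
            seed=seeds[hr],
        )
        trace = simulate(seq, params=params, solver=config.solver)
        df = summarize(trace)
        summaries[hr] = df
        aggs[hr] = aggregate(df)
        non_ejecting[hr] = aggs[hr].attrs.get("n_non_ejecting", 0)
        if hr in (min(config.hr_list), max(config.hr_list)):
            P = trace.pressures
            keep = trace.t - trace.t[0] <= 8.0
            repr_traces[hr] = pd.DataFrame(
                {"t": trace.t[keep], "p_lv": P["p_lv"][keep], "p_sas": P["p_sas"][keep]}
            )
        del trace
    table = _index_table(aggs)
    manifest = {
        "version": _pkg_version,
        "seed": config.seed,
        "hr_seeds": {f"{hr:g}": s for hr, s in seeds.items()},
        "hr_list": [float(h) for h in config.hr_list],
        "beats_per_hr": config.beats_per_hr,
        "cv": config.cv,
        "tau_fraction": config.tau_fraction,
        "rr_min": config.rr_min,
        "solver": asdict(config.solver),
        "parameters": {k: float(v) for k, v in asdict(params).items()},
        "non_ejecting_beats": {f"{hr:g}": int(n) for hr, n in non_ejecting.items()},
    }
    return SweepResult(
        table=table, summaries=summaries, manifest=manifest, repr_traces=repr_traces
    )


def stationarity_check(summaries: pd.DataFrame, z_threshold: float = 3.0) -> pd.DataFrame:
    """Split-half stationarity diagnostic for a beat-summary stream.

    For each index, reports the difference between first- and second-half
    means in units of its standard error; ``flagged`` marks indices whose
    |z| exceeds ``z_threshold`` (drift, i.e. the run has not reached
    statistical stationarity).
    """
    if len(summaries) < 1000:
        raise ValueError("stationarity check needs >= 1000 beats")
    num = summaries.drop(columns=["ejecting"], errors="ignore").select_dtypes("number")
    half = len(num) // 2
    a, b = num.iloc[:half], num.iloc[half:]
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    z = (b.mean() - a.mean()) / se
    out = pd.DataFrame({"z": z, "flagged": z.abs() > z_threshold})
    return out


def render_outputs(result: SweepResult, outdir) -> list[Path]:
    """Write the index table, per-beat summaries, manifest and figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tpath = outdir / "table1.csv"
    result.table.to_csv(tpath, float_format="%.6g")
    written.append(tpath)
    for hr, df in result.summaries.items():
        p = outdir / f"beats_{hr:g}.csv"
        write_summary_csv(df, p)
        written.append(p)
    mpath = outdir / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)
    written.append(mpath)

    hrs = result.manifest["hr_list"]
    cv = result.manifest["cv"]
    tau_fraction = result.manifest["tau_fraction"]

    # Fig 1: RR-interval densities per HR
    fig, ax = plt.subplots(figsize=(6, 4))
    tt = np.linspace(0.05, 2.5, 800)
    for hr in hrs:
        if cv > 0:
            pars = exgauss_from_moments(60.0 / hr, cv, tau_fraction)
            ax.plot(tt, exgauss_pdf(tt, pars), label=f"{hr:g} bpm")
    ax.set_xlabel("RR (s)")
    ax.set_ylabel("pdf (1/s)")
    ax.legend()
    ax.set_title(f"RR distributions (cv = {cv})")
    fig.tight_layout()
    fig.savefig(outdir / "fig1.png", dpi=150)
    plt.close(fig)
    written.append(outdir / "fig1.png")

    def _hr_panel(ax, rows, ylabel):
        for label in rows:
            means = [result.table.loc[label, f"mean_{hr:g}"] for hr in hrs]
            ax.plot(hrs, means, "o-", label=label.split(" [")[0])
        ax.set_xlabel("HR (bpm)")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=7)

    # Figs 2-3: LV and systemic arterial pressures vs HR + sample series
    for num, rows, series_col, name in (
        (2, ["P_lv [mmHg]", "P_lves [mmHg]", "P_lved [mmHg]"], "p_lv", "fig2.png"),
        (3, ["P_sas [mmHg]", "P_sas,syst [mmHg]", "P_sas,dias [mmHg]"], "p_sas", "fig3.png"),
    ):
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        _hr_panel(ax1, rows, "pressure (mmHg)")
        for hr, tr in result.repr_traces.items():
            ax2.plot(tr["t"], tr[series_col], lw=0.8, label=f"{hr:g} bpm")
        ax2.set_xlabel("t (s)")
        ax2.set_ylabel("pressure (mmHg)")
        ax2.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / name, dpi=150)
        plt.close(fig)
        written.append(outdir / name)

    # Fig 4: the seven mechano-energetic panels
    panels = [
        "SV [ml]", "EF [%]", "SW [J]", "RPP [mmHg/min]",
        "TTI/min [mmHg s/min]", "PVA/min [J/min]", "SW/PVA [%]",
    ]
    fig, axes = plt.subplots(2, 4, figsize=(14, 6))
    for ax, label in zip(axes.ravel(), panels):
        means = [result.table.loc[label, f"mean_{hr:g}"] for hr in hrs]
        sds = [result.table.loc[label, f"sd_{hr:g}"] for hr in hrs]
        ax.errorbar(hrs, means, yerr=sds, fmt="o-", capsize=3)
        ax.set_title(label, fontsize=9)
        ax.set_xlabel("HR (bpm)")
    axes.ravel()[-1].axis("off")
    fig.tight_layout()
    fig.savefig(outdir / "fig4.png", dpi=150)
    plt.close(fig)
    written.append(outdir / "fig4.png")
    return written
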