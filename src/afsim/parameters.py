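"""Physiological parameter set for the closed-loop lumped circulation.

The circulation is a closed hydraulic loop of eight storage compartments —
four heart chambers (time-varying elastance; passive atria) and four
vascular beds (linear compliance): systemic arteries, systemic veins,
pulmonary arteries, pulmonary veins.  The four valves are pressure-gated
resistive diodes with blood inertance, so transvalvular flow can decelerate
against an adverse gradient but never reverses.

Units are clinical throughout: pressure mmHg, volume mL, time s, resistance
mmHg·s/mL, compliance mL/mmHg, inertance mmHg·s²/mL, elastance mmHg/mL.

The default set ships as ``data/default_params.yaml``; it was calibrated so
that a regular rhythm at 70 bpm lands on textbook-normal left-heart values
(ejection fraction in the 55-70% band, systolic arterial pressure
100-130 mmHg) with passive atria.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from importlib import resources

import numpy as np
import yaml

__all__ = ["ModelParameters", "load_params", "save_params", "default_params"]


@dataclass(frozen=True)
class ModelParameters:
    # Left ventricle: time-varying elastance between lv_emin and lv_emax.
    lv_emax: float
    lv_emin: float
    lv_v0: float
    # Left atrium: constant elastance (passive — no atrial kick, as in AF).
    la_e: float
    la_v0: float
    # Right ventricle.
    rv_emax: float
    rv_emin: float
    rv_v0: float
    # Right atrium (passive).
    ra_e: float
    ra_v0: float
    # Systolic duration law T_sys = tsys_k * sqrt(RR).
    tsys_k: float
    # Fraction of T_sys at which ventricular activation peaks (rise phase
    # sin^2 up to the peak, cos^2 relaxation after it).
    act_peak_frac: float
    # Valves: open-state resistance and inertance (mitral, aortic,
    # tricuspid, pulmonary).
    mi_r: float
    mi_l: float
    ao_r: float
    ao_l: float
    ti_r: float
    ti_l: float
    po_r: float
    po_l: float
    # Vascular compartments: compliance and unstressed volume.
    sa_c: float
    sa_v0: float
    sv_c: float
    sv_v0: float
    pa_c: float
    pa_v0: float
    pv_c: float
    pv_v0: float
    # Inter-compartment resistances: systemic arteries->veins,
    # veins->right atrium, pulmonary arteries->veins, veins->left atrium.
    r_sys: float
    r_ven: float
    r_pul: float
    r_pv: float
    # Total blood volume in the closed loop (sets mean circulatory filling).
    total_volume: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite")
        positive = [
            f.name
            for f in fields(self)
            if f.name not in ("lv_v0", "la_v0", "rv_v0", "ra_v0",
                              "sa_v0", "sv_v0", "pa_v0", "pv_v0")
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if self.lv_emax < self.lv_emin or self.rv_emax < self.rv_emin:
            raise ValueError("ventricular E_max must be >= E_min")
        if not 0 < self.act_peak_frac < 1:
            raise ValueError("act_peak_frac must lie strictly in (0, 1)")

    def as_array(self) -> np.ndarray:
        """Flat float64 vector in declaration order (fast path for the ODE
        right-hand side)."""
        return np.array(
            [getattr(self, f.name) for f in fields(self)], dtype=float
        )

    def replace(self, **kw) -> "ModelParameters":
        d = asdict(self)
        d.update(kw)
        return ModelParameters(**d)


_FIELD_NAMES = [f.name for f in fields(ModelParameters)]
#: Index of each parameter in :meth:`ModelParameters.as_array`.
PARAM_INDEX = {name: i for i, name in enumerate(_FIELD_NAMES)}


def load_params(path=None) -> ModelParameters:
    """Load a parameter set from YAML; unknown keys are rejected.

    With ``path=None`` the packaged default set is loaded.
    """
    if path is None:
        text = (
            resources.files("afsim").joinpath("data/default_params.yaml")
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("parameter file must be a YAML mapping")
    unknown = set(raw) - set(_FIELD_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(_FIELD_NAMES) - set(raw)
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    return ModelParameters(**{k: float(v) for k, v in raw.items()})


def save_params(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)


def default_params() -> ModelParameters:
    """The packaged, calibrated default parameter set."""
    return load_params(None)
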