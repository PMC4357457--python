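"""Stochastic RR-interval sequences for simulated atrial fibrillation.

During AF the beat-to-beat interval is well described by an exponentially
modified Gaussian (exGaussian): the sum of a Gaussian and an independent
exponential random variable, giving the characteristic right-skewed
distribution of irregular ventricular response.  Sequences are parameterised
by the nominal mean heart rate (mean RR = 60/HR) and by the coefficient of
variation cv = sd/mean, which is held at the AF-typical value 0.24 by
default regardless of rate.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ExGaussParams",
    "RRSequence",
    "exgauss_from_moments",
    "sample_rr",
    "exgauss_pdf",
    "write_rr_csv",
    "read_rr_csv",
]

#: AF-typical coefficient of variation of the RR distribution.
AF_CV = 0.24

#: Default fraction of the RR variance carried by the exponential component.
DEFAULT_TAU_FRACTION = 0.5

#: Default physiological floor on RR (s), a ventricular refractoriness proxy.
DEFAULT_RR_MIN = 0.3


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of an exponentially modified Gaussian RR distribution.

    Attributes
    ----------
    mu_g : float
        Mean of the Gaussian component (s).
    sigma_g : float
        Standard deviation of the Gaussian component (s).
    tau : float
        Mean of the exponential component (s).

    The distribution mean is ``mu_g + tau`` and its variance
    ``sigma_g**2 + tau**2``.
    """

    mu_g: float
    sigma_g: float
    tau: float

    @property
    def mean(self) -> float:
        return self.mu_g + self.tau

    @property
    def sd(self) -> float:
        return float(np.hypot(self.sigma_g, self.tau))

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    @property
    def is_degenerate(self) -> bool:
        return self.sigma_g == 0.0 and self.tau == 0.0


@dataclass(frozen=True)
class RRSequence:
    """A seeded sequence of beat intervals (s) with its target moments."""

    intervals: np.ndarray
    hr_nominal: float
    cv_target: float
    seed: int | None = None
    tau_fraction: float = DEFAULT_TAU_FRACTION

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals", np.asarray(self.intervals, dtype=float)
        )
        if self.intervals.ndim != 1 or self.intervals.size == 0:
            raise ValueError("intervals must be a nonempty 1-D array")
        if np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def mean_rr(self) -> float:
        return float(self.intervals.mean())

    @property
    def cv(self) -> float:
        return float(self.intervals.std(ddof=1) / self.intervals.mean())


def exgauss_from_moments(
    mean_rr: float,
    cv: float,
    tau_fraction: float = DEFAULT_TAU_FRACTION,
) -> ExGaussParams:
    """Solve the exGaussian parameters from target mean and cv.

    The two moment constraints ``mu_g + tau = mean_rr`` and
    ``sigma_g^2 + tau^2 = (cv * mean_rr)^2`` leave one degree of freedom:
    ``tau_fraction`` fixes the share of the total variance assigned to the
    exponential component (``tau^2 = tau_fraction * total variance``).

    ``cv = 0`` returns the degenerate point mass at ``mean_rr`` (regular
    rhythm), useful for periodic steady-state checks.
    """
    if not np.isfinite(mean_rr) or mean_rr <= 0:
        raise ValueError(f"mean_rr must be positive, got {mean_rr!r}")
    if not 0 <= cv < 1:
        raise ValueError(f"cv must satisfy 0 <= cv < 1, got {cv!r}")
    if not 0 < tau_fraction < 1:
        raise ValueError(
            f"tau_fraction must lie strictly in (0, 1), got {tau_fraction!r}"
        )
    if cv == 0:
        return ExGaussParams(mu_g=mean_rr, sigma_g=0.0, tau=0.0)
    sd = cv * mean_rr
    tau = np.sqrt(tau_fraction) * sd
    sigma_g = np.sqrt(1.0 - tau_fraction) * sd
    return ExGaussParams(mu_g=mean_rr - tau, sigma_g=sigma_g, tau=tau)


def _truncated_moments(params: ExGaussParams, rr_min: float) -> tuple[float, float]:
    """Mean and sd of the exGaussian conditioned on exceeding ``rr_min``."""
    k = params.tau / params.sigma_g
    dist = stats.exponnorm(k, loc=params.mu_g, scale=params.sigma_g)
    p_keep = dist.sf(rr_min)
    m1 = dist.expect(lambda t: t, lb=rr_min) / p_keep
    m2 = dist.expect(lambda t: t * t, lb=rr_min) / p_keep
    return m1, float(np.sqrt(max(m2 - m1 * m1, 0.0)))


def _correct_for_floor(
    mean_rr: float, cv: float, tau_fraction: float, rr_min: float
) -> ExGaussParams:
    """Adjust the underlying exGaussian so the floored (left-truncated)
    distribution still has the target mean and cv.

    Rejection at the physiological floor trims the left tail, which would
    otherwise inflate the mean and deflate the cv at fast rates.  A short
    fixed-point iteration on the underlying (mean, sd) removes that bias;
    when the floor is far in the tail the loop exits after one pass.
    """
    target_sd = cv * mean_rr
    mu, sd = mean_rr, target_sd
    params = exgauss_from_moments(mu, sd / mu, tau_fraction)
    for _ in range(40):
        m, s = _truncated_moments(params, rr_min)
        if abs(m - mean_rr) < 1e-10 * mean_rr and abs(s - target_sd) < 1e-10 * mean_rr:
            break
        mu += mean_rr - m
        sd *= target_sd / s
        if mu <= sd:  # keep cv of the underlying distribution < 1
            raise ValueError(
                f"cannot match mean={mean_rr}, cv={cv} under rr_min={rr_min}"
            )
        params = exgauss_from_moments(mu, sd / mu, tau_fraction)
    return params


def sample_rr(
    n: int,
    hr: float,
    cv: float = AF_CV,
    tau_fraction: float = DEFAULT_TAU_FRACTION,
    rr_min: float = DEFAULT_RR_MIN,
    seed: int | np.random.Generator | None = None,
) -> RRSequence:
    """Draw ``n`` AF-like RR intervals at nominal mean heart rate ``hr`` (bpm).

    Draws are Gaussian(mu_g, sigma_g) + Exponential(tau); draws below
    ``rr_min`` are rejected and redrawn from the same seeded stream, so the
    sequence is fully reproducible for a fixed integer seed.  The underlying
    parameters are pre-adjusted so that the floored distribution keeps the
    requested mean and cv (the floor otherwise biases both at fast rates).

    Raises
    ------
    ValueError
        If the rejection rate exceeds 50% (parameters incompatible with the
        physiological floor), or on invalid arguments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if hr <= 0:
        raise ValueError("hr must be positive")
    if rr_min < 0:
        raise ValueError("rr_min must be >= 0")
    if not (50 <= hr <= 130):
        warnings.warn(
            f"hr={hr} bpm is outside the studied 50-130 bpm range",
            stacklevel=2,
        )
    if 60.0 / hr <= rr_min:
        raise ValueError("target mean RR lies at or below rr_min")
    params = exgauss_from_moments(60.0 / hr, cv, tau_fraction)
    if cv > 0 and rr_min > 0:
        params = _correct_for_floor(60.0 / hr, cv, tau_fraction, rr_min)
    rng = np.random.default_rng(seed)

    if params.is_degenerate:
        if params.mu_g < rr_min:
            raise ValueError("degenerate RR below rr_min")
        intervals = np.full(n, params.mu_g)
    else:
        intervals = np.empty(n)
        filled = 0
        drawn = 0
        while filled < n:
            m = n - filled
            draws = rng.normal(params.mu_g, params.sigma_g, m)
            draws += rng.exponential(params.tau, m)
            drawn += m
            ok = draws >= rr_min
            k = int(ok.sum())
            intervals[filled : filled + k] = draws[ok]
            filled += k
            if drawn >= 2 * n and filled < drawn // 2:
                raise ValueError(
                    "rejection rate above 50%: exGaussian parameters are "
                    f"incompatible with rr_min={rr_min}"
                )
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return RRSequence(
        intervals=intervals,
        hr_nominal=hr,
        cv_target=cv,
        seed=seed_out,
        tau_fraction=tau_fraction,
    )


def exgauss_pdf(t: np.ndarray | float, params: ExGaussParams) -> np.ndarray:
    """exGaussian probability density (1/s) evaluated at ``t``.

    Raises ``ValueError`` for the degenerate (zero-variance) spec, which has
    no density.
    """
    if params.sigma_g <= 0 or params.tau <= 0:
        raise ValueError("degenerate exGaussian has no density")
    k = params.tau / params.sigma_g
    return stats.exponnorm.pdf(t, k, loc=params.mu_g, scale=params.sigma_g)


def write_rr_csv(seq: RRSequence, path) -> None:
    """Write one interval per row (s, 6 decimals); the header comment records
    the generating parameters."""
    header = (
        f"# hr={seq.hr_nominal} cv={seq.cv_target} "
        f"tau_fraction={seq.tau_fraction} seed={seq.seed}\n"
        "rr_s\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for rr in seq.intervals:
            fh.write(f"{rr:.6f}\n")


def read_rr_csv(path) -> RRSequence:
    """Read a sequence written by :func:`write_rr_csv`."""
    with open(path) as fh:
        first = fh.readline()
        rest = fh.read()
    meta: dict[str, float] = {}
    if first.startswith("#"):
        for tok in first[1:].split():
            key, _, val = tok.partition("=")
            if val and val != "None":
                meta[key] = float(val)
    body = io.StringIO(rest)
    intervals = np.loadtxt(body, skiprows=1, ndmin=1)
    seed = meta.get("seed")
    return RRSequence(
        intervals=intervals,
        hr_nominal=meta.get("hr", 60.0 / float(np.mean(intervals))),
        cv_target=meta.get("cv", float(np.std(intervals) / np.mean(intervals))),
        seed=int(seed) if seed is not None else None,
        tau_fraction=meta.get("tau_fraction", DEFAULT_TAU_FRACTION),
    )
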