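"""Synthetic herd generator for the milking-prediction tasks.

Each cow's milk-flow curve is a saturating rise followed by an
exponential decline::

    f(t) = plateau * (1 - exp(-t / rise_tau))          t <= decline_start
    f(t) = f(decline_start) * exp(-(t - decline_start) / decline_tau)

The milking cluster detaches shortly after the flow falls through the
detachment threshold (default 600 g/min): the machine reacts with a small
delay, and the effective threshold jitters session-to-session with vacuum
fluctuation. All recorded quantities derive from this curve in closed
form: the four early-window mean flows, peak flow and time, the session
yield (the integral), the average milking time (AMT, crossing time plus
machine delay plus attachment overhead), and the removal flow (the mean
flow over the final seconds before the cluster actually comes off). The
delayed, averaged removal flow is what lets recorded values fall below
the set threshold, creating the negative class of the removal-flow task.

The statistical structure mirrors what the prediction tasks assume:

* a per-cow productivity latent drives both the 10-day average yield and
  the decline onset (``yield_link_strength``), so prior yield predicts
  AMT but carries nothing about the decline *rate*;
* the decline time-constant is correlated with the plateau flow
  (``flow_decline_corr``), so the early flow windows — which observe the
  plateau and the rise — carry the removal-flow signal.

Severing ``yield_link_strength`` therefore removes the yield column's
information about AMT while leaving the removal-flow task untouched.

Latent medians are calibrated to parlour scale: the default (slow-herd)
configuration centres AMT near 8 min with peak flows around 3.7 kg/min;
:func:`general_config` centres AMT near 5 min with peaks around 6.4
kg/min.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .records import MilkingRecord

__all__ = [
    "FlowCurveParams",
    "HerdSimConfig",
    "DegenerateSessionError",
    "flow_at",
    "curve_integral",
    "window_mean_flow",
    "crossing_time",
    "derive_session",
    "simulate_herd",
    "slow_cow_config",
    "general_config",
    "high_signal_config",
    "herd_to_csv",
]


class DegenerateSessionError(ValueError):
    """The detachment threshold is at or above the attainable flow."""


@dataclass(frozen=True)
class FlowCurveParams:
    """Parameters of one cow's flow curve; flows g/min, times seconds."""

    plateau_flow: float
    rise_tau: float
    decline_start: float
    decline_tau: float
    detachment_threshold: float = 600.0

    def __post_init__(self) -> None:
        for name in ("plateau_flow", "rise_tau", "decline_start", "decline_tau",
                     "detachment_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def flow_at_decline_start(self) -> float:
        return self.plateau_flow * (1.0 - math.exp(-self.decline_start / self.rise_tau))


def flow_at(t: float | np.ndarray, p: FlowCurveParams) -> float | np.ndarray:
    """Instantaneous flow (g/min) at time t (s); continuous at the break."""
    t = np.asarray(t, dtype=float)
    rise = p.plateau_flow * (1.0 - np.exp(-t / p.rise_tau))
    f_ds = p.flow_at_decline_start
    decline = f_ds * np.exp(-(t - p.decline_start) / p.decline_tau)
    out = np.where(t <= p.decline_start, rise, decline)
    return float(out) if out.ndim == 0 else out


def curve_integral(p: FlowCurveParams, t0: float, t1: float) -> float:
    """Closed-form integral of the flow curve over [t0, t1] (g*s/min)."""
    if t0 < 0 or t1 < t0:
        raise ValueError("need 0 <= t0 <= t1")
    total = 0.0
    ds = p.decline_start
    a, b = t0, min(t1, ds)
    if b > a:  # rising/plateau segment
        total += p.plateau_flow * (
            (b - a) + p.rise_tau * (math.exp(-b / p.rise_tau) - math.exp(-a / p.rise_tau))
        )
    a, b = max(t0, ds), t1
    if b > a:  # decline segment
        f_ds = p.flow_at_decline_start
        total += f_ds * p.decline_tau * (
            math.exp(-(a - ds) / p.decline_tau) - math.exp(-(b - ds) / p.decline_tau)
        )
    return total


def window_mean_flow(p: FlowCurveParams, t0: float, t1: float) -> float:
    """Mean flow (g/min) over the window [t0, t1] seconds."""
    if not 0 <= t0 < t1:
        raise ValueError("need 0 <= t0 < t1")
    return curve_integral(p, t0, t1) / (t1 - t0)


def crossing_time(p: FlowCurveParams, threshold: float | None = None) -> float:
    """First time (s) after the decline onset when flow falls to ``threshold``."""
    thr = p.detachment_threshold if threshold is None else threshold
    f_ds = p.flow_at_decline_start
    if thr >= f_ds:
        raise DegenerateSessionError(
            f"threshold {thr:.1f} g/min is at or above the attainable flow "
            f"{f_ds:.1f} g/min: immediate detachment"
        )
    return p.decline_start + p.decline_tau * math.log(f_ds / thr)


def derive_session(
    p: FlowCurveParams,
    attachment_overhead_s: float = 30.0,
    removal_window_s: float = 15.0,
    detach_delay_s: float = 0.0,
) -> dict[str, float]:
    """Derive all measured session quantities from the flow curve.

    Returns a dict with the numeric :class:`~milkpredict.records.MilkingRecord`
    fields except ``avg_yield_10d`` (a cow-level quantity). The AMT includes
    the attachment overhead; yields are converted g -> kg.
    """
    t_cross = crossing_time(p)
    t_det = t_cross + detach_delay_s
    f_ds = p.flow_at_decline_start
    removal_flow = window_mean_flow(p, max(0.0, t_det - removal_window_s), t_det)
    return {
        "milk_yield": curve_integral(p, 0.0, t_det) / 60.0 / 1000.0,  # g*s/min -> kg
        "amt": (t_det + attachment_overhead_s) / 60.0,
        "flow_0_15": window_mean_flow(p, 0.0, 15.0),
        "flow_15_30": window_mean_flow(p, 15.0, 30.0),
        "flow_30_60": window_mean_flow(p, 30.0, 60.0),
        "flow_60_120": window_mean_flow(p, 60.0, 120.0),
        "peak_flow": f_ds,
        "peak_time": p.decline_start / 60.0,
        "removal_flow": removal_flow,
    }


@dataclass
class HerdSimConfig:
    """Herd-level generative settings.

    Latents are log-normal, parameterized by median and log-sd.
    ``yield_link_strength`` is the correlation between the productivity
    latent (which sets ``avg_yield_10d``) and the decline-onset latent;
    ``flow_decline_corr`` is the correlation between the plateau latent
    and the decline time-constant latent. ``noise_cv`` is the coefficient
    of variation of multiplicative measurement noise on reported flows;
    ``threshold_cv`` is the log-sd of the session's effective detachment
    threshold.

    The defaults describe the slow herd studied for the AMT task (AMT
    centred near the 8-min cut).
    """

    n_cows: int = 300
    sessions_per_cow: int = 2
    plateau_flow_median: float = 3700.0
    plateau_flow_sigma: float = 0.25
    rise_tau_median: float = 25.0
    rise_tau_sigma: float = 0.30
    decline_start_median: float = 170.0
    decline_start_sigma: float = 0.45
    decline_tau_median: float = 150.0
    decline_tau_sigma: float = 0.35
    flow_decline_corr: float = 0.95
    yield_link_strength: float = 0.95
    yield_base_kg: float = 18.5
    yield_sigma: float = 0.25
    yield_noise_sd: float = 0.05
    noise_cv: float = 0.05
    detachment_threshold: float = 600.0
    threshold_cv: float = 0.08
    attachment_overhead_s: float = 30.0
    removal_window_s: float = 30.0
    detach_delay_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 1:
            raise ValueError("n_cows must be >= 1")
        if self.sessions_per_cow < 1:
            raise ValueError("sessions_per_cow must be >= 1")
        if self.noise_cv < 0 or self.threshold_cv < 0 or self.yield_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")
        for name in ("flow_decline_corr", "yield_link_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "plateau_flow_median", "plateau_flow_sigma", "rise_tau_median",
            "rise_tau_sigma", "decline_start_median", "decline_start_sigma",
            "decline_tau_median", "decline_tau_sigma", "yield_base_kg",
            "yield_sigma", "detachment_threshold", "attachment_overhead_s",
            "removal_window_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.detach_delay_s < 0:
            raise ValueError("detach_delay_s must be non-negative")


def slow_cow_config(**overrides) -> HerdSimConfig:
    """The slow herd (AMT near 8 min, peak flow ~3.7 kg/min): the defaults."""
    return HerdSimConfig(**overrides)


def general_config(**overrides) -> HerdSimConfig:
    """Whole-herd scale: AMT near 5 min, peak flow ~6.4 kg/min."""
    params = dict(
        plateau_flow_median=6400.0,
        decline_start_median=130.0,
        decline_start_sigma=0.30,
        decline_tau_median=55.0,
    )
    params.update(overrides)
    return HerdSimConfig(**params)


def high_signal_config(**overrides) -> HerdSimConfig:
    """Slow herd with the latent links saturated and jitter minimized.

    With the productivity latent fully determining the decline onset and
    the plateau fully determining the decline rate, AMT is a nearly
    deterministic function of the observable features; residual error
    comes only from measurement noise and threshold jitter.
    """
    params = dict(
        flow_decline_corr=1.0,
        yield_link_strength=1.0,
        threshold_cv=0.02,
        yield_noise_sd=0.01,
        noise_cv=0.05,
    )
    params.update(overrides)
    return HerdSimConfig(**params)


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def simulate_herd(config: HerdSimConfig) -> list[MilkingRecord]:
    """Generate one herd; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records: list[MilkingRecord] = []
    w = config.yield_link_strength
    rho = config.flow_decline_corr
    noisy_fields = (
        "flow_0_15", "flow_15_30", "flow_30_60", "flow_60_120",
        "peak_flow", "removal_flow",
    )
    for cow in range(config.n_cows):
        z_yield = rng.normal()
        z_plateau = rng.normal()
        z_onset = w * z_yield + math.sqrt(1.0 - w * w) * rng.normal()
        z_decline = rho * z_plateau + math.sqrt(1.0 - rho * rho) * rng.normal()
        p = FlowCurveParams(
            plateau_flow=config.plateau_flow_median
            * math.exp(config.plateau_flow_sigma * z_plateau),
            rise_tau=config.rise_tau_median
            * math.exp(config.rise_tau_sigma * rng.normal()),
            decline_start=config.decline_start_median
            * math.exp(config.decline_start_sigma * z_onset),
            decline_tau=config.decline_tau_median
            * math.exp(config.decline_tau_sigma * z_decline),
            detachment_threshold=config.detachment_threshold,
        )
        avg_yield = config.yield_base_kg * math.exp(
            config.yield_sigma * z_yield + config.yield_noise_sd * rng.normal()
        )
        for session in range(config.sessions_per_cow):
            thr_eff = config.detachment_threshold * math.exp(
                config.threshold_cv * rng.normal()
            )
            # a threshold above the attainable flow would detach immediately;
            # cap it just below so the session stays well defined
            thr_eff = min(thr_eff, 0.95 * p.flow_at_decline_start)
            p_eff = dataclasses.replace(p, detachment_threshold=thr_eff)
            fields = derive_session(
                p_eff,
                attachment_overhead_s=config.attachment_overhead_s,
                removal_window_s=config.removal_window_s,
                detach_delay_s=config.detach_delay_s,
            )
            for name in noisy_fields:
                fields[name] *= float(_lognormal_noise(rng, config.noise_cv))
            records.append(
                MilkingRecord(
                    cow_id=f"cow{cow:04d}",
                    session_time=f"day{session // 2 + 1:02d}-"
                    + ("am" if session % 2 == 0 else "pm"),
                    avg_yield_10d=avg_yield,
                    **fields,
                )
            )
    return records


def herd_to_csv(records, path, config: HerdSimConfig | None = None) -> None:
    """Write a herd CSV; optionally prepend a provenance header comment."""
    from .records import records_to_frame

    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write("# milkpredict synthetic herd\n")
            for key, value in dataclasses.asdict(config).items():
                fh.write(f"# {key} = {value}\n")
        records_to_frame(records).to_csv(fh, index=False, float_format="%.10g")
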