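"""Synthetic batch-fermentation generator with fault injection.

The generator emulates normal glutamate fed-batch runs.  A smooth
metabolic-activity pulse a(t) (fast rise over the first ~5 h, slow
exponential decay, normalized to peak 1) sets the shape of every
trajectory; a batch's *metabolic capacity* c_b -- tightly linked to its
final titer A_b, which is drawn over the configured range -- scales its
gas exchange; and a slow Ornstein-Uhlenbeck fluctuation ou(t) adds
metabolic variability shared between gas exchange and product formation.
Per batch b:

    CER_b(t)  = c_b * [ base(t) + 122 * a(t) * (1 + 0.05 * ou(t)) ] + noise
    OUR_b(t)  = f_b * CER_b(t) + noise          (f_b near 1)
    DO_b(t)   = 52 - 30 * a(t) + noise          (common demand-shaped
                                                 drawdown of the DO loop)
    G_b(t)    = A_b * F(t) + kappa * int_0^t a(s) ou(s) ds

where F is the normalized integral of a (so the true glutamate curve
saturates at A_b).  Because capacity scales both the activity peak and the
maintenance baseline of CER/OUR, gas exchange genuinely encodes how
productive a batch is -- not merely what time it is -- which is what lets
an additive model estimate production from the online channels.  pH sits
at ~7.1 (ammonia titration), stirring follows the oxygen demand within
400-900 rpm and temperature holds at ~32.1 degC.

Two fault scenarios can be injected: a stirring-speed collapse
(SS < 300 rpm, DO ~ 0, CER/OUR < 20 mol m^-3 h^-1) and a nitrogen-source
substitution (NaOH instead of ammonia water: CER/OUR sag to a maintenance
level and production stalls while pH, DO, SS and Temp all look normal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .batch import ONLINE_CHANNELS, BatchConfig, FaultSpec, FermentationBatch

__all__ = [
    "simulate_normal_batch",
    "inject_fault",
    "make_study_set",
    "simulate_regression_table",
]

_CER_AMPLITUDE = 122.0  # mol m^-3 h^-1 above baseline at the activity peak
_CER_BASE_START = 50.0  # baseline drifts 50 -> 37 over the batch
_CER_BASE_DRIFT = -13.0
_CER_FLUCT = 0.05  # relative OU fluctuation of gas exchange at peak activity
_CAPACITY_SPAN = 0.16  # relative spread of metabolic capacity across batches
_COND_NOISE = 0.05  # how loosely capacity tracks the batch's titer quality
_PROD_FLUCT = 0.488  # g/L/h production-rate fluctuation per unit a(t)*ou(t)
_OU_TAU_H = 3.0  # correlation time of the metabolic fluctuation
_NITROGEN_FLOOR = 25.0  # maintenance-level CER without a nitrogen source
_DO_BASE = 52.0  # % air saturation with the culture at rest
_DO_DEPLETION = 30.0  # % DO drawn down at peak oxygen demand
_SS_BASE = 450.0
_SS_PER_CER = 2.8


def _activity_shape(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Metabolic activity pulse, normalized to peak 1."""
    raw = (1.0 - np.exp(-((t / rise) ** 2))) * np.exp(-t / decay)
    peak = raw.max()
    return raw / peak if peak > 0 else raw


def _ou_process(rng, n: int, step_h: float, tau_h: float) -> np.ndarray:
    """Discretized Ornstein-Uhlenbeck path, zero start, stationary sd 1,
    clipped at +-2.5 so a single batch cannot wander arbitrarily far."""
    w = np.zeros(n)
    shocks = rng.normal(0.0, np.sqrt(2.0 * step_h / tau_h), n)
    decay = 1.0 - step_h / tau_h
    for i in range(1, n):
        w[i] = w[i - 1] * decay + shocks[i]
    return np.clip(w, -2.5, 2.5)


def simulate_normal_batch(
    config: BatchConfig | None = None,
    batch_id: str = "normal-01",
    quality: float | None = None,
) -> FermentationBatch:
    """Simulate one normal fermentation batch.

    Offline glutamate follows a smooth saturating curve from ~0 g/L to a
    final titer drawn in ``config.final_glutamate_range``; online channels
    follow the activity-pulse physiology described in the module docstring.
    Two calls with the same config (seed included) are identical.
    """
    cfg = config or BatchConfig()
    rng = np.random.default_rng(cfg.seed)

    step_h = cfg.online_interval_min / 60.0
    n_online = int(round(cfg.duration_h / step_h)) + 1
    t_on = np.arange(n_online) * step_h
    n_off = int(round(cfg.duration_h / cfg.offline_interval_h)) + 1
    t_off = np.arange(n_off) * cfg.offline_interval_h

    # batch-level draws: the batch's metabolic capacity sets both its gas
    # exchange amplitude and its final titer, so CER/OUR genuinely encode
    # how productive a batch is -- not merely what time it is.  The DO
    # setpoint is an independent operating condition.
    lo, hi = cfg.final_glutamate_range
    drawn = rng.uniform(0.0, 1.0)  # always drawn, so the stream is stable
    if quality is None:
        quality = drawn
    if not 0.0 <= quality <= 1.0:
        raise ValueError("quality must lie in [0, 1]")
    final_titer = lo + (hi - lo) * quality
    u_cer = np.clip(quality + rng.normal(0.0, _COND_NOISE), 0.0, 1.0)
    capacity = 1.0 + _CAPACITY_SPAN * (u_cer - 0.5)
    our_factor = rng.uniform(0.98, 1.02)
    rise = rng.uniform(2.98, 3.02)
    decay = rng.uniform(7.25, 7.35)

    activity = _activity_shape(t_on, rise, decay)
    cum = cumulative_trapezoid(activity, t_on, initial=0.0)
    frac_produced = cum / cum[-1]  # F(t): nominal fraction of titer made
    fluct = _ou_process(rng, n_online, step_h, _OU_TAU_H)
    prod_rate_fluct = _PROD_FLUCT * activity * fluct
    glut_true = np.clip(
        final_titer * frac_produced
        + cumulative_trapezoid(prod_rate_fluct, t_on, initial=0.0),
        0.0,
        None,
    )

    # maintenance respiration also scales with the batch's metabolic
    # capacity, so the quality signal persists into the late run
    baseline = capacity * (
        _CER_BASE_START + _CER_BASE_DRIFT * t_on / cfg.duration_h
    )
    demand = _CER_AMPLITUDE * capacity * activity
    cer_clean = baseline + demand * (1.0 + _CER_FLUCT * fluct)
    sd = cfg.noise_sd_online
    cer = cer_clean + rng.normal(0, sd["CER"], n_online)
    our = our_factor * cer_clean + rng.normal(0, sd["OUR"], n_online)
    # the DO control loop follows a common demand-shaped drawdown; it does
    # not carry batch identity
    do = np.clip(
        _DO_BASE - _DO_DEPLETION * activity + rng.normal(0, sd["DO"], n_online),
        0.0,
        100.0,
    )
    ph = 7.1 + rng.normal(0, sd["pH"], n_online)
    ss = np.clip(
        _SS_BASE
        + _SS_PER_CER * (cer_clean - baseline)
        + rng.normal(0, sd["SS"], n_online),
        400.0,
        900.0,
    )
    temp = np.clip(
        32.1
        + 0.08 * np.sin(2 * np.pi * t_on / 24.0)
        + rng.normal(0, sd["Temp"], n_online),
        31.8,
        32.4,
    )

    idx = np.rint(t_off / step_h).astype(int)
    glut_off = np.clip(
        glut_true[idx] + rng.normal(0, cfg.noise_sd_glutamate, n_off), 0.0, None
    )

    offline = pd.DataFrame({"time_h": t_off, "glutamate": glut_off})
    online = pd.DataFrame(
        {
            "time_h": t_on,
            "CER": cer,
            "DO": do,
            "OUR": our,
            "pH": ph,
            "SS": ss,
            "Temp": temp,
        }
    )
    return FermentationBatch(batch_id, offline, online).validate()


def inject_fault(batch: FermentationBatch, fault: FaultSpec) -> FermentationBatch:
    """Return a new batch with ``fault`` imprinted on its signals.

    Online channels and offline glutamate outside the (open) fault window
    are copied verbatim; offline increments that overlap the window are
    scaled by ``1 - severity * overlap_fraction``, so accumulation stalls
    in-window and resumes at the normal rate (from the depressed level)
    afterwards.  The input batch is not modified.
    """
    if fault.end_h > batch.duration_h + 1e-9:
        raise ValueError(
            f"fault window [{fault.start_h}, {fault.end_h}] h exceeds batch "
            f"duration {batch.duration_h} h"
        )
    out = batch.copy()
    t = out.online["time_h"].to_numpy(float)
    win = (t > fault.start_h) & (t < fault.end_h)

    if fault.kind == "stirring_drop":
        ss = out.online["SS"].to_numpy(float)
        do = out.online["DO"].to_numpy(float)
        cer = out.online["CER"].to_numpy(float)
        our = out.online["OUR"].to_numpy(float)
        ratio = np.divide(our, cer, out=np.ones_like(our), where=cer != 0)
        cer_f = 8.0 + 0.03 * cer
        out.online.loc[win, "SS"] = (230.0 + 0.05 * (ss - 400.0))[win]
        out.online.loc[win, "DO"] = (1.0 + 0.02 * do)[win]
        out.online.loc[win, "CER"] = cer_f[win]
        out.online.loc[win, "OUR"] = (ratio * cer_f)[win]
    elif fault.kind == "nitrogen_substitution":
        cer = out.online["CER"].to_numpy(float)
        our = out.online["OUR"].to_numpy(float)
        ratio = np.divide(our, cer, out=np.ones_like(our), where=cer != 0)
        cer_f = _NITROGEN_FLOOR + (1.0 - fault.severity) * (cer - _NITROGEN_FLOOR)
        out.online.loc[win, "CER"] = cer_f[win]
        out.online.loc[win, "OUR"] = (ratio * cer_f)[win]
    else:  # pragma: no cover - FaultSpec already validates
        raise ValueError(f"unknown fault kind {fault.kind!r}")

    # stall glutamate accumulation over the overlapped offline increments
    t_off = out.offline["time_h"].to_numpy(float)
    g = out.offline["glutamate"].to_numpy(float)
    if len(g) > 1:
        incr = np.diff(g)
        left, right = t_off[:-1], t_off[1:]
        overlap = np.clip(
            np.minimum(right, fault.end_h) - np.maximum(left, fault.start_h),
            0.0,
            None,
        ) / (right - left)
        g_new = np.concatenate(
            [[g[0]], g[0] + np.cumsum(incr * (1.0 - fault.severity * overlap))]
        )
        out.offline["glutamate"] = np.clip(g_new, 0.0, None)

    out.faults = list(batch.faults) + [fault]
    return out.validate()


def make_study_set(
    n_normal: int,
    fault_specs: list[FaultSpec] | None = None,
    base_seed: int = 0,
    config: BatchConfig | None = None,
) -> list[FermentationBatch]:
    """Build a reproducible study set: ``n_normal`` normal batches plus one
    faulted batch per entry of ``fault_specs``.

    Per-batch seeds are derived deterministically from ``base_seed`` so the
    same arguments always reproduce the same set.  Batch qualities are
    stratified over the titer range (a fermentation campaign deliberately
    spans operating conditions rather than replicating one point), with the
    assignment shuffled by the seed.
    """
    if n_normal < 2:
        raise ValueError("need at least 2 normal batches")
    fault_specs = fault_specs or []
    base = config or BatchConfig()
    seed_rng = np.random.default_rng(base_seed)
    n_total = n_normal + len(fault_specs)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_total)
    strata = (np.arange(n_total) + 0.5) / n_total
    qualities = np.clip(
        seed_rng.permutation(strata)
        + seed_rng.uniform(-0.5 / n_total, 0.5 / n_total, n_total),
        0.0,
        1.0,
    )

    batches = []
    for i in range(n_normal):
        cfg = BatchConfig(
            **{**_config_kwargs(base), "seed": int(seeds[i])}
        )
        batches.append(
            simulate_normal_batch(
                cfg, batch_id=f"normal-{i + 1:02d}", quality=float(qualities[i])
            )
        )
    for j, spec in enumerate(fault_specs):
        cfg = BatchConfig(
            **{**_config_kwargs(base), "seed": int(seeds[n_normal + j])}
        )
        clean = simulate_normal_batch(
            cfg,
            batch_id=f"fault-{spec.kind}-{j + 1:02d}",
            quality=float(qualities[n_normal + j]),
        )
        batches.append(inject_fault(clean, spec))
    return batches


def _config_kwargs(cfg: BatchConfig) -> dict:
    return {
        "duration_h": cfg.duration_h,
        "offline_interval_h": cfg.offline_interval_h,
        "online_interval_min": cfg.online_interval_min,
        "final_glutamate_range": cfg.final_glutamate_range,
        "noise_sd_glutamate": cfg.noise_sd_glutamate,
        "noise_sd_online": dict(cfg.noise_sd_online),
        "seed": cfg.seed,
    }


def simulate_regression_table(
    n: int,
    seed: int = 0,
    noise_sd: float = 2.0,
    null_extra: bool = True,
) -> pd.DataFrame:
    """Regression benchmark table with known additive structure.

    Covariates are drawn independently over realistic instrument ranges and
    the response depends on smooth functions of T, DO, OUR and CER only;
    SS, pH and Temp (present when ``null_extra``) carry no signal.  Used by
    model-selection and significance calibration studies.
    """
    rng = np.random.default_rng(seed)
    T = rng.uniform(0, 30, n)
    DO = rng.uniform(10, 55, n)
    OUR = rng.uniform(35, 180, n)
    CER = rng.uniform(40, 170, n)
    y = (
        10.0
        + 35.0 / (1.0 + np.exp(-(T - 10.0) / 4.0))
        + 5.0 * np.sin(np.pi * (DO - 10.0) / 45.0)
        + 8.0 * np.tanh((OUR - 100.0) / 40.0)
        + 1.2e-3 * (CER - 100.0) ** 2
        + rng.normal(0, noise_sd, n)
    )
    table = pd.DataFrame(
        {"batch_id": "sim", "time_h": T, "T": T, "DO": DO, "OUR": OUR, "CER": CER}
    )
    if null_extra:
        table["SS"] = rng.uniform(400, 900, n)
        table["pH"] = rng.uniform(6.9, 7.3, n)
        table["Temp"] = rng.uniform(31.8, 32.4, n)
    table["glutamate"] = y
    return table
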