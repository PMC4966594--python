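"""Residual-bootstrap prediction band for glutamate production.

Around the fitted additive model, pseudo-responses are generated by
resampling training residuals with replacement:

    Y*(t)     = Yhat(t)     + eps*_t        (training rows, t = 1..N)
    Y*(N+h)   = Yhat(N+h)   + eps*_{N+h}    (prediction grid, h = 1..H)

each bootstrap replicate refits the model on (X(t), Y*(t)) and records the
prediction errors e'*_{N+h} = Y*(N+h) - Yhat*(N+h).  Their empirical
distribution G-tilde per grid point gives the pointwise 100(1-alpha)%
band

    [ Yhat(N+h) + G~^{-1}(alpha/2),  Yhat(N+h) + G~^{-1}(1-alpha/2) ].

The band is indexed by fermentation time, with the grid-time covariate
values ("reference trajectory") conventionally taken as the across-batch
mean online trajectory of the training runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import ONLINE_CHANNELS, FermentationBatch
from .gam import GAMFit, _Design, _finalize, predict

__all__ = [
    "BandConfig",
    "BootstrapBand",
    "batch_reference_trajectories",
    "empirical_quantile",
    "mean_online_trajectory",
    "build_band",
    "band_covers",
    "read_band_csv",
]


def empirical_quantile(values, q: float):
    """Linear-interpolation empirical quantile; q=0/1 give min/max."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empirical_quantile of empty sequence")
    q = np.asarray(q, float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile level must lie in [0, 1]")
    return np.quantile(values, q, method="linear")


@dataclass(frozen=True)
class BandConfig:
    """Bootstrap-band settings.

    ``B`` replicates at level ``alpha`` (default 1000 and 0.05: the 95 %
    band from 1000 refits).  ``grid`` defaults to the offline assay grid
    of the reference trajectory.  ``standardize`` resamples
    leverage-adjusted residuals e_i / sqrt(1 - h_ii) instead of raw ones,
    undoing the in-sample shrinkage of fitted residuals (the usual
    modified-residual refinement of the residual bootstrap).
    ``refit=False`` skips the per-replicate model refit (prediction errors
    then reduce to resampled residuals), which exists for oracle checks,
    not production use.  ``pool_errors`` pools e'* across grid points
    instead of per-point quantiles.
    """

    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    grid: tuple | None = None
    standardize: bool = True
    refit: bool = True
    pool_errors: bool = False
    min_success_frac: float = 0.9

    def __post_init__(self):
        if self.B < 50:
            raise ValueError("B must be at least 50")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class BootstrapBand:
    """Pointwise lower/upper band, center curve and bootstrap mean."""

    grid_times: np.ndarray
    center: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    boot_mean: np.ndarray
    error_lo: np.ndarray  # G~^{-1}(alpha/2) per grid point
    error_hi: np.ndarray  # G~^{-1}(1-alpha/2) per grid point
    alpha: float
    n_replicates: int

    def interp(self, times) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lower, center, upper) linearly interpolated at ``times``.

        Times outside the grid range are rejected: the band is only
        defined over the fermentation window it was built for.
        """
        times = np.asarray(times, float)
        lo, hi = self.grid_times[0], self.grid_times[-1]
        if np.any(times < lo - 1e-9) or np.any(times > hi + 1e-9):
            raise ValueError(
                f"time outside band grid range [{lo}, {hi}] h"
            )
        return (
            np.interp(times, self.grid_times, self.lower),
            np.interp(times, self.grid_times, self.center),
            np.interp(times, self.grid_times, self.upper),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.grid_times,
                "lower": self.lower,
                "center": self.center,
                "boot_mean": self.boot_mean,
                "upper": self.upper,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def to_json(self, path: str) -> None:
        payload = {
            "alpha": self.alpha,
            "n_replicates": self.n_replicates,
            "grid_times": self.grid_times.tolist(),
            "center": self.center.tolist(),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "boot_mean": self.boot_mean.tolist(),
            "error_lo": self.error_lo.tolist(),
            "error_hi": self.error_hi.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def read_band_csv(path: str, alpha: float = 0.05) -> BootstrapBand:
    """Reload a band exported with :meth:`BootstrapBand.to_csv`."""
    frame = pd.read_csv(path)
    need = ["time_h", "lower", "center", "boot_mean", "upper"]
    missing = [c for c in need if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return BootstrapBand(
        grid_times=frame["time_h"].to_numpy(float),
        center=frame["center"].to_numpy(float),
        lower=frame["lower"].to_numpy(float),
        upper=frame["upper"].to_numpy(float),
        boot_mean=frame["boot_mean"].to_numpy(float),
        error_lo=frame["lower"].to_numpy(float) - frame["center"].to_numpy(float),
        error_hi=frame["upper"].to_numpy(float) - frame["center"].to_numpy(float),
        alpha=alpha,
        n_replicates=0,
    )


def mean_online_trajectory(
    batches: list[FermentationBatch], grid_times: np.ndarray | None = None
) -> pd.DataFrame:
    """Across-batch mean online trajectory sampled at ``grid_times``.

    Defaults to the offline assay grid of the first batch.  The result has
    a ``time_h`` column, a matching fermentation-time covariate ``T`` and
    one column per online channel (nearest records averaged over batches).
    """
    if not batches:
        raise ValueError("need at least one batch")
    if grid_times is None:
        grid_times = batches[0].offline["time_h"].to_numpy(float)
    grid_times = np.asarray(grid_times, float)
    acc = {ch: np.zeros(len(grid_times)) for ch in ONLINE_CHANNELS}
    for batch in batches:
        t_on = batch.online["time_h"].to_numpy(float)
        idx = np.clip(np.searchsorted(t_on, grid_times), 1, len(t_on) - 1)
        nearest = np.where(
            np.abs(t_on[idx - 1] - grid_times) <= np.abs(t_on[idx] - grid_times),
            idx - 1,
            idx,
        )
        for ch in ONLINE_CHANNELS:
            acc[ch] += batch.online[ch].to_numpy(float)[nearest]
    frame = pd.DataFrame({"time_h": grid_times, "T": grid_times})
    for ch in ONLINE_CHANNELS:
        frame[ch] = acc[ch] / len(batches)
    return frame


def batch_reference_trajectories(
    batches: list[FermentationBatch], grid_times: np.ndarray | None = None
) -> pd.DataFrame:
    """Every batch's own online trajectory sampled at ``grid_times``,
    concatenated (several rows per grid time).

    Feeding this to :func:`build_band` yields the monitoring band: its
    error distribution includes the between-batch spread of estimate
    curves, so normal batches stay inside at the nominal level while fault
    excursions leave it.
    """
    frames = [
        mean_online_trajectory([batch], grid_times).assign(batch_id=batch.batch_id)
        for batch in batches
    ]
    return pd.concat(frames, ignore_index=True).sort_values(
        ["time_h", "batch_id"], kind="stable"
    ).reset_index(drop=True)


def _reoptimize_lambdas(design: _Design, lam0: np.ndarray, sweeps: int = 2) -> np.ndarray:
    """Light coordinate search around warm-start lambdas (bootstrap refits)."""
    factors = np.array([1e-3, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0, 1e3])
    lam = lam0.copy()
    best = design.gcv(lam)
    for _ in range(sweeps):
        improved = False
        for j in range(len(lam)):
            trial = lam.copy()
            scores = np.empty(len(factors))
            for g, f in enumerate(factors):
                trial[j] = lam0[j] * f
                scores[g] = design.gcv(trial)
            k = int(np.argmin(scores))
            if scores[k] < best - 1e-12:
                lam[j], best, improved = lam0[j] * factors[k], scores[k], True
        if not improved:
            break
    return lam


def build_band(
    fit: GAMFit,
    table,
    reference_covariates: pd.DataFrame,
    config: BandConfig | None = None,
) -> BootstrapBand:
    """Build the residual-bootstrap band around ``fit``.

    ``table`` must be the training table the fit was produced from;
    ``reference_covariates`` supplies the model covariates (and
    ``time_h``) at each grid time.  With one row per grid time this is the
    textbook construction: the band is centred on the model estimate at
    those covariates and its half-widths are quantiles of the bootstrap
    prediction errors.  The frame may also carry *several* rows per grid
    time (e.g. every training batch's own covariate trajectory, see
    :func:`batch_reference_trajectories`); the band is then centred on the
    across-row mean estimate and the error distribution additionally
    absorbs the between-trajectory spread, so that every normal batch's
    estimate curve is contained at the nominal level -- the band drawn
    against fermentation time for monitoring.

    Replicate substreams derive deterministically from ``config.seed`` so
    results are independent of execution order.  Replicates whose refit
    fails are skipped; fewer than ``min_success_frac * B`` successes
    aborts.
    """
    cfg = config or BandConfig()
    ref = reference_covariates
    if cfg.grid is not None:
        keep = np.isin(ref["time_h"].to_numpy(float), np.asarray(cfg.grid, float))
        ref = ref.loc[keep].reset_index(drop=True)
        if not len(ref):
            raise ValueError("cfg.grid has no overlap with reference times")
    ref_times = ref["time_h"].to_numpy(float)
    grid_times, group_idx = np.unique(ref_times, return_inverse=True)
    H, R = len(grid_times), len(ref_times)
    counts = np.bincount(group_idx, minlength=H)

    row_pred = predict(fit, ref)  # estimate at each reference row
    center = np.bincount(group_idx, weights=row_pred, minlength=H) / counts
    offsets = row_pred - center[group_idx]  # between-trajectory spread

    residuals = fit.residuals
    if cfg.standardize and fit.leverages is not None:
        residuals = residuals / np.sqrt(1.0 - np.clip(fit.leverages, 0.0, 0.95))
    n = len(residuals)

    if np.ptp(residuals) == 0 and not offsets.any():
        warnings.warn("residuals have zero spread; band degenerates to width 0")
        zero = np.zeros(H)
        return BootstrapBand(
            grid_times, center, center.copy(), center.copy(),
            center.copy(), zero, zero.copy(), cfg.alpha, cfg.B,
        )

    # rebuild the design once; replicates only swap the response vector
    bases = {t.variable: t.basis for t in fit.terms if t.basis is not None}
    linear = all(t.kind == "linear" for t in fit.terms)
    design = _Design(
        table, fit.variables, basis_dim=0, linear=linear,
        bases=bases if not linear else None,
    )
    lam0 = np.array([0.0 if np.isinf(t.lam) else t.lam for t in fit.terms])

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.B)
    errors = np.empty((cfg.B, R))
    boot_centers = np.empty((cfg.B, H))
    ok = np.zeros(cfg.B, bool)
    for b in range(cfg.B):
        rng = np.random.default_rng(children[b])
        eps_t = residuals[rng.integers(0, n, n)]
        eps_h = residuals[rng.integers(0, n, R)]
        y_star_h = row_pred + eps_h
        try:
            if cfg.refit:
                y_star = fit.fitted + eps_t
                design_b = design.with_response(y_star)
                lam_b = _reoptimize_lambdas(design_b, lam0)
                refit = _finalize(design_b, lam_b)
                yhat_star_h = predict(refit, ref)
            else:
                yhat_star_h = row_pred
        except (ValueError, np.linalg.LinAlgError):
            continue
        # prediction error of each reference row relative to the band center
        errors[b] = (y_star_h - yhat_star_h) + offsets
        boot_centers[b] = (
            np.bincount(group_idx, weights=yhat_star_h, minlength=H) / counts
        )
        ok[b] = True

    n_ok = int(ok.sum())
    if n_ok < cfg.min_success_frac * cfg.B:
        raise ValueError(
            f"only {n_ok}/{cfg.B} bootstrap refits succeeded "
            f"(need >= {cfg.min_success_frac:.0%})"
        )
    errors = errors[ok]
    boot_centers = boot_centers[ok]
    if cfg.pool_errors:
        lo_q = float(empirical_quantile(errors.ravel(), cfg.alpha / 2))
        hi_q = float(empirical_quantile(errors.ravel(), 1 - cfg.alpha / 2))
        error_lo = np.full(H, lo_q)
        error_hi = np.full(H, hi_q)
    else:
        error_lo = np.empty(H)
        error_hi = np.empty(H)
        for g in range(H):
            pool = errors[:, group_idx == g].ravel()
            error_lo[g] = empirical_quantile(pool, cfg.alpha / 2)
            error_hi[g] = empirical_quantile(pool, 1 - cfg.alpha / 2)
    return BootstrapBand(
        grid_times=grid_times,
        center=center,
        lower=center + error_lo,
        upper=center + error_hi,
        boot_mean=boot_centers.mean(axis=0),
        error_lo=error_lo,
        error_hi=error_hi,
        alpha=cfg.alpha,
        n_replicates=n_ok,
    )


def band_covers(
    band: BootstrapBand, times, values
) -> tuple[np.ndarray, float]:
    """Per-point in-band booleans and the covered fraction."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    lower, _, upper = band.interp(times)
    inside = (values >= lower) & (values <= upper)
    return inside, float(inside.mean())
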