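"""Container types for fermentation batch time series.

A batch couples a sparse *offline* glutamate assay series (drawn samples,
every 2 h by default) with a dense *online* process-parameter log
(instrument channels, every 6 min by default).  Online channels follow the
conventional abbreviations: CER (carbon dioxide evolution rate,
mol m^-3 h^-1), DO (dissolved oxygen, % air saturation), OUR (oxygen uptake
rate, mol m^-3 h^-1), pH, SS (stirring speed, rpm) and Temp (broth
temperature, degC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical online channel order used throughout the package
ONLINE_CHANNELS = ("CER", "DO", "OUR", "pH", "SS", "Temp")

FAULT_KINDS = ("stirring_drop", "nitrogen_substitution")


@dataclass(frozen=True)
class BatchConfig:
    """Configuration of one simulated fermentation batch.

    Parameters
    ----------
    duration_h
        Total batch duration in hours.
    offline_interval_h
        Spacing of offline glutamate assays, hours.  Must sit on the
        online grid (a positive multiple of ``online_interval_min / 60``).
    online_interval_min
        Spacing of online instrument records, minutes.
    final_glutamate_range
        (low, high) g/L envelope from which the batch's final titer is
        drawn uniformly.
    noise_sd_glutamate
        Additive Gaussian measurement noise on offline assays, g/L.
    noise_sd_online
        Per-channel additive Gaussian noise scales (keys from
        :data:`ONLINE_CHANNELS`); unspecified channels use defaults.
    seed
        Seed for all batch randomness.
    """

    duration_h: float = 30.0
    offline_interval_h: float = 2.0
    online_interval_min: float = 6.0
    final_glutamate_range: tuple[float, float] = (75.0, 85.0)
    noise_sd_glutamate: float = 1.5
    noise_sd_online: dict = field(
        default_factory=lambda: dict(DEFAULT_ONLINE_NOISE_SD)
    )
    seed: int = 0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.online_interval_min <= 0:
            raise ValueError("online_interval_min must be positive")
        step_h = self.online_interval_min / 60.0
        ratio = self.offline_interval_h / step_h
        if self.offline_interval_h <= 0 or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "offline_interval_h must be a positive multiple of the "
                "online interval"
            )
        lo, hi = self.final_glutamate_range
        if not lo < hi:
            raise ValueError("final_glutamate_range must satisfy low < high")
        sd = dict(DEFAULT_ONLINE_NOISE_SD)
        sd.update(self.noise_sd_online)
        object.__setattr__(self, "noise_sd_online", sd)


DEFAULT_ONLINE_NOISE_SD = {
    "CER": 2.0,
    "DO": 2.5,
    "OUR": 2.0,
    "pH": 0.03,
    "SS": 5.0,
    "Temp": 0.03,
}


@dataclass(frozen=True)
class FaultSpec:
    """A process fault injected over a time window.

    ``stirring_drop`` emulates an agitation failure: stirring collapses
    below 300 rpm, the broth goes oxygen-starved (DO near 0 %) and gas
    exchange (CER, OUR) falls below 20 mol m^-3 h^-1.
    ``nitrogen_substitution`` emulates titrating with NaOH instead of
    ammonia water: pH, DO, SS and Temp all stay in their normal ranges but
    the culture is starved of nitrogen, so CER/OUR sag and glutamate
    synthesis stalls.

    ``severity`` in (0, 1] scales how strongly glutamate accumulation is
    suppressed inside the window (1.0 = production fully stalled).
    """

    kind: str
    start_h: float
    end_h: float
    severity: float = 1.0

    def __post_init__(self):
        if self.kind not in FAULT_KINDS:
            raise ValueError(
                f"unknown fault kind {self.kind!r}; expected one of {FAULT_KINDS}"
            )
        if not 0 <= self.start_h < self.end_h:
            raise ValueError("fault window must satisfy 0 <= start_h < end_h")
        if not 0 < self.severity <= 1:
            raise ValueError("severity must lie in (0, 1]")


@dataclass
class FermentationBatch:
    """One batch: offline glutamate series, online channel log, fault notes.

    ``offline`` has columns ``time_h, glutamate``; ``online`` has columns
    ``time_h`` plus :data:`ONLINE_CHANNELS`.  Fault annotations record what
    was injected by the simulator (empty for a normal batch); real plant
    data would leave them empty.
    """

    batch_id: str
    offline: pd.DataFrame
    online: pd.DataFrame
    faults: list[FaultSpec] = field(default_factory=list)

    def validate(self) -> "FermentationBatch":
        for name, frame, cols in (
            ("offline", self.offline, ["time_h", "glutamate"]),
            ("online", self.online, ["time_h", *ONLINE_CHANNELS]),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise ValueError(f"{name} table missing column(s) {missing}")
            t = frame["time_h"].to_numpy(float)
            if len(t) and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} time axis must be strictly increasing")
        if (self.offline["glutamate"] < 0).any():
            raise ValueError("glutamate must be non-negative")
        do = self.online["DO"]
        if ((do < 0) | (do > 100)).any():
            raise ValueError("DO must lie in [0, 100] %")
        t_on = self.online["time_h"].to_numpy(float)
        t_off = self.offline["time_h"].to_numpy(float)
        if len(t_off) and (t_off.min() < t_on.min() or t_off.max() > t_on.max()):
            raise ValueError("online series must cover all offline times")
        return self

    def copy(self) -> "FermentationBatch":
        return replace(
            self,
            offline=self.offline.copy(),
            online=self.online.copy(),
            faults=list(self.faults),
        )

    @property
    def duration_h(self) -> float:
        return float(self.online["time_h"].iloc[-1])
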