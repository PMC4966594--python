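"""Online fault diagnosis against the bootstrap prediction band.

Glutamate production is estimated from the streaming online parameters at
every instrument record (6 min cadence) via the fitted additive model; a
fault is a (debounced) run of timepoints where that estimate leaves the
95 % band.  An event has a start (first out-of-band point) and an end
(estimate returns into the band), or stays open if the stream ends while
still out of band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band import BootstrapBand
from .gam import GAMFit, predict

__all__ = [
    "FaultEvent",
    "FaultReport",
    "estimate_online",
    "detect_faults",
    "summarize_report",
]


@dataclass(frozen=True)
class FaultEvent:
    """One maximal out-of-band excursion.

    ``end_h`` is ``None`` while the excursion is unresolved at stream end;
    ``peak_excursion`` is the largest distance (g/L) beyond the violated
    band edge.
    """

    start_h: float
    end_h: float | None
    peak_excursion: float

    @property
    def duration_h(self) -> float | None:
        return None if self.end_h is None else self.end_h - self.start_h


@dataclass
class FaultReport:
    """Per-timepoint monitoring records plus the detected fault events."""

    batch_id: str
    records: pd.DataFrame  # time_h, estimate, lower, upper, in_band
    events: list[FaultEvent] = field(default_factory=list)

    @property
    def out_fraction(self) -> float:
        """Pre-debounce fraction of out-of-band timepoints."""
        return float(1.0 - self.records["in_band"].mean())


def estimate_online(fit: GAMFit, online: pd.DataFrame) -> pd.DataFrame:
    """Estimate glutamate production at every online record.

    The stream must provide every model covariate; fermentation time is
    taken from ``time_h`` when the model uses covariate ``T``.  Estimates
    are clamped below at 0 g/L (titers are non-negative).
    """
    frame = online.copy()
    if "T" in fit.variables and "T" not in frame.columns:
        frame["T"] = frame["time_h"]
    missing = [v for v in fit.variables if v not in frame.columns]
    if missing:
        raise ValueError(f"online stream missing model covariate(s) {missing}")
    estimate = np.clip(predict(fit, frame), 0.0, None)
    return pd.DataFrame({"time_h": online["time_h"].to_numpy(float), "estimate": estimate})


def detect_faults(
    estimates: pd.DataFrame,
    band: BootstrapBand,
    debounce: int = 1,
    batch_id: str = "",
) -> FaultReport:
    """Flag intervals where the online estimate leaves the band.

    A point is out-of-band iff estimate < lower or estimate > upper at the
    linearly interpolated band.  An event opens at the first point of a
    run of at least ``debounce`` consecutive out-of-band points and closes
    at the first point of the next run of at least ``debounce`` in-band
    points (shorter blips in either direction are ignored).
    """
    if len(estimates) == 0:
        raise ValueError("empty estimate stream")
    if debounce < 1:
        raise ValueError("debounce must be >= 1")
    times = estimates["time_h"].to_numpy(float)
    est = estimates["estimate"].to_numpy(float)
    lower, _, upper = band.interp(times)
    below = est < lower
    above = est > upper
    out = below | above
    excursion = np.where(below, lower - est, np.where(above, est - upper, 0.0))

    records = pd.DataFrame(
        {
            "time_h": times,
            "estimate": est,
            "lower": lower,
            "upper": upper,
            "in_band": ~out,
        }
    )

    events: list[FaultEvent] = []
    n = len(out)
    i = 0
    in_event = False
    start = peak = None
    run_target = None
    while i < n:
        state = out[i]
        # length of the run of identical states starting at i
        j = i
        while j < n and out[j] == state:
            j += 1
        run = j - i
        if not in_event and state and run >= debounce:
            in_event = True
            start = times[i]
            peak = excursion[i:j].max()
        elif in_event:
            if state:
                peak = max(peak, excursion[i:j].max())
            elif run >= debounce:
                events.append(FaultEvent(start, float(times[i]), float(peak)))
                in_event = False
        i = j
    if in_event:
        events.append(FaultEvent(start, None, float(peak)))
    return FaultReport(batch_id=batch_id, records=records, events=events)


def summarize_report(report: FaultReport) -> tuple[str, dict]:
    """Human-readable summary and its machine-readable JSON twin."""
    lines = [f"batch {report.batch_id or '<unnamed>'}:"]
    payload_events = []
    if not report.events:
        lines.append("  no faults detected")
    for k, ev in enumerate(report.events, start=1):
        end = "open" if ev.end_h is None else f"{ev.end_h:.2f} h"
        dur = "open" if ev.duration_h is None else f"{ev.duration_h:.2f} h"
        lines.append(
            f"  fault {k}: start {ev.start_h:.2f} h, end {end}, "
            f"duration {dur}, peak excursion {ev.peak_excursion:.2f} g/L"
        )
        payload_events.append(
            {
                "start_h": ev.start_h,
                "end_h": ev.end_h,
                "duration_h": ev.duration_h,
                "peak_excursion": ev.peak_excursion,
            }
        )
    payload = {
        "batch_id": report.batch_id,
        "n_events": len(report.events),
        "out_fraction": report.out_fraction,
        "events": payload_events,
    }
    return "\n".join(lines), payload


def write_report_json(report: FaultReport, path: str) -> None:
    _, payload = summarize_report(report)
    payload["records"] = {
        col: report.records[col].tolist() for col in report.records.columns
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
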