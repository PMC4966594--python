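"""CSV round-tripping of batches and offline/online alignment.

File convention: each batch is a pair of headered CSV files,
``<batch_id>_offline.csv`` (columns ``time_h, glutamate``) and
``<batch_id>_online.csv`` (columns ``time_h, CER, DO, OUR, pH, SS, Temp``).
The training table aligns every offline assay with the nearest-in-time
online record (within a tolerance) and pools rows across batches.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .batch import ONLINE_CHANNELS, BatchConfig, FermentationBatch

OFFLINE_COLUMNS = ["time_h", "glutamate"]
ONLINE_COLUMNS = ["time_h", *ONLINE_CHANNELS]

#: columns of a training table, in order
TRAINING_COLUMNS = ["batch_id", "time_h", "T", "DO", "OUR", "CER", "SS", "pH", "Temp", "glutamate"]

#: default alignment tolerance: half the 6 min online interval
ALIGN_TOLERANCE_H = 3.0 / 60.0


def _read_table(path: str, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in required:
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            row = int(frame.index[values.isna()][0])
            raise ValueError(f"{path}: non-numeric value in column {col!r} (row {row})")
        frame[col] = values.astype(float)
    t = frame["time_h"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: column 'time_h' must be strictly increasing")
    return frame[required]


def read_batch_csv(path_prefix: str) -> FermentationBatch:
    """Read ``<prefix>_offline.csv`` + ``<prefix>_online.csv`` into a batch.

    ``path_prefix`` may be a directory plus batch id, e.g. ``runs/normal-01``.
    """
    offline = _read_table(path_prefix + "_offline.csv", OFFLINE_COLUMNS)
    online = _read_table(path_prefix + "_online.csv", ONLINE_COLUMNS)
    batch_id = os.path.basename(path_prefix)
    return FermentationBatch(batch_id, offline, online)


def write_batch_csv(batch: FermentationBatch, directory: str) -> tuple[str, str]:
    """Write a batch as its two CSV files; returns the written paths."""
    os.makedirs(directory, exist_ok=True)
    off_path = os.path.join(directory, f"{batch.batch_id}_offline.csv")
    on_path = os.path.join(directory, f"{batch.batch_id}_online.csv")
    batch.offline[OFFLINE_COLUMNS].to_csv(off_path, index=False, float_format="%.12g")
    batch.online[ONLINE_COLUMNS].to_csv(on_path, index=False, float_format="%.12g")
    return off_path, on_path


def align_offline_online(
    batches: list[FermentationBatch], tolerance_h: float = ALIGN_TOLERANCE_H
) -> pd.DataFrame:
    """Pool batches into one training table.

    Each offline assay is paired with the nearest-in-time online record of
    the same batch; a gap beyond ``tolerance_h`` is an error naming the
    batch and time.  Fermentation time enters the table as covariate ``T``.
    Rows are sorted by (batch_id, time) so the result does not depend on
    the input order of ``batches``.
    """
    rows = []
    for batch in sorted(batches, key=lambda b: b.batch_id):
        t_on = batch.online["time_h"].to_numpy(float)
        t_off = batch.offline["time_h"].to_numpy(float)
        glut = batch.offline["glutamate"].to_numpy(float)
        idx = np.searchsorted(t_on, t_off)
        idx = np.clip(idx, 1, len(t_on) - 1)
        nearest = np.where(
            np.abs(t_on[idx - 1] - t_off) <= np.abs(t_on[idx] - t_off), idx - 1, idx
        )
        gaps = np.abs(t_on[nearest] - t_off)
        if np.any(gaps > tolerance_h + 1e-12):
            k = int(np.argmax(gaps > tolerance_h + 1e-12))
            raise ValueError(
                f"batch {batch.batch_id!r}: no online record within "
                f"{tolerance_h * 60:.1f} min of offline time {t_off[k]} h"
            )
        online_rows = batch.online.iloc[nearest]
        for k in range(len(t_off)):
            rec = online_rows.iloc[k]
            rows.append(
                {
                    "batch_id": batch.batch_id,
                    "time_h": t_off[k],
                    "T": t_off[k],
                    "DO": rec["DO"],
                    "OUR": rec["OUR"],
                    "CER": rec["CER"],
                    "SS": rec["SS"],
                    "pH": rec["pH"],
                    "Temp": rec["Temp"],
                    "glutamate": glut[k],
                }
            )
    table = pd.DataFrame(rows, columns=TRAINING_COLUMNS)
    if table.isna().any().any():
        raise ValueError("training table contains missing values")
    return table.reset_index(drop=True)


def split_batches(
    batches: list[FermentationBatch], test_index: int | str = "median"
) -> tuple[list[FermentationBatch], FermentationBatch]:
    """Batch-level train/test split: hold out one whole batch.

    The default holds out the batch with the median final titer, i.e. a
    batch run at an interior operating condition -- validating at the edge
    of the covariate range would measure extrapolation rather than the
    model's calibration.  Pass an integer index (into the id-sorted list)
    to override.
    """
    if len(batches) < 2:
        raise ValueError("need at least two batches to split")
    ordered = sorted(batches, key=lambda b: b.batch_id)
    if test_index == "median":
        finals = np.array([b.offline["glutamate"].iloc[-1] for b in ordered])
        test = ordered[int(np.argsort(finals)[len(finals) // 2])]
    else:
        test = ordered[test_index]
    train = [b for b in ordered if b.batch_id != test.batch_id]
    return train, test


def load_batch_config(path: str) -> BatchConfig:
    """Read a :class:`BatchConfig` from a YAML (or JSON) mapping."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping of BatchConfig fields")
    if "final_glutamate_range" in payload:
        payload["final_glutamate_range"] = tuple(payload["final_glutamate_range"])
    return BatchConfig(**payload)
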