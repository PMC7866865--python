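"""Duration equalization, long-record windowing and sampling-rate decimation.

Every trial is reduced to exactly 10 s: ordinary records are trimmed top and
tail in equal measure, while the single-trial 100-s walking/jogging records
are expanded into five non-overlapping 10-s windows so each activity ends up
with five trials.  Lower sampling rates are produced by stride decimation —
literal removal of samples, keeping every k-th starting from the first —
with no anti-alias filter by default.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import IMURecord
from .io import ActivityCatalog, ConversionConfig, read_sisfall_record

#: Target rates of the sampling-rate study; every entry divides 200 Hz.
DEFAULT_RATE_GRID = (1, 2, 5, 10, 20, 50, 100, 200)

#: Non-overlapping 10-s windows cut from 100-s records: [5,15), [25,35), ...
DEFAULT_WINDOW_OFFSETS = (5.0, 25.0, 45.0, 65.0, 85.0)

TARGET_DURATION_S = 10.0


def _shift_impact_meta(record: IMURecord, start_sample: int) -> dict:
    """Shift a ground-truth impact time when the record start moves."""
    meta = dict(record.meta)
    if "impact_time_s" in meta:
        meta["impact_time_s"] = meta["impact_time_s"] - start_sample / record.sampling_rate
    return meta


def trim_record(record: IMURecord, target_duration: float = TARGET_DURATION_S) -> IMURecord:
    """Cut a record down to ``target_duration`` seconds, centered.

    Removes ``floor((N - M) / 2)`` samples from the head and the remainder
    from the tail, keeping a contiguous block of exactly
    ``round(target_duration * rate)`` samples.
    """
    m = int(round(target_duration * record.sampling_rate))
    n = record.n_samples
    if n < m:
        raise ValueError(
            f"record {record.activity_code}/{record.subject_id} has "
            f"{n / record.sampling_rate:.2f} s, shorter than target "
            f"{target_duration} s"
        )
    head = (n - m) // 2
    out = record.slice(head, head + m)
    out.meta = _shift_impact_meta(record, head)
    return out


def extract_windows(
    record: IMURecord,
    offsets: Sequence[float] = DEFAULT_WINDOW_OFFSETS,
    width: float = TARGET_DURATION_S,
) -> list[IMURecord]:
    """Cut non-overlapping ``width``-second windows at the given offsets.

    The outputs are renumbered as trials 1..len(offsets), replacing the
    single original trial index.
    """
    rate = record.sampling_rate
    n = record.n_samples
    w = int(round(width * rate))
    windows = []
    for i, offset in enumerate(offsets, start=1):
        start = int(round(offset * rate))
        stop = start + w
        if stop > n:
            raise ValueError(
                f"record of {record.duration:.1f} s too short for window "
                f"[{offset}, {offset + width}) s"
            )
        win = record.slice(start, stop)
        win.trial_index = i
        win.meta = _shift_impact_meta(record, start)
        win.meta["window_offset_s"] = float(offset)
        windows.append(win)
    return windows


def decimate(
    record: IMURecord, target_rate: float, anti_alias: bool = False
) -> IMURecord:
    """Reduce the sampling rate by keeping every k-th sample.

    ``target_rate`` must divide the source rate exactly.  The default is
    pure stride decimation anchored at the first sample; ``anti_alias=True``
    applies a zero-phase low-pass filter first (scipy's decimator).
    """
    ratio = record.sampling_rate / target_rate
    stride = int(round(ratio))
    if stride < 1 or not math.isclose(ratio, stride, rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"target rate {target_rate} Hz does not divide source rate "
            f"{record.sampling_rate} Hz"
        )
    if stride == 1:
        return record
    if anti_alias:
        accel = _signal.decimate(record.accel, stride, axis=0, zero_phase=True)
        gyro = _signal.decimate(record.gyro, stride, axis=0, zero_phase=True)
    else:
        accel = record.accel[::stride]
        gyro = record.gyro[::stride]
    return record.with_(accel=accel, gyro=gyro, sampling_rate=float(target_rate))


def prepare_records(
    records: Iterable[IMURecord],
    catalog: ActivityCatalog,
    target_rate: float,
    target_duration: float = TARGET_DURATION_S,
    window_offsets: Sequence[float] = DEFAULT_WINDOW_OFFSETS,
) -> list[IMURecord]:
    """Equalize, window-expand and decimate an in-memory record stream.

    Long-record activities are expanded into one sub-record per window
    offset; everything else is trimmed to ``target_duration``.  Every output
    has exactly ``target_duration * target_rate`` samples.
    """
    out: list[IMURecord] = []
    for record in records:
        info = catalog[record.activity_code]
        if info.long_record:
            pieces = extract_windows(record, window_offsets, target_duration)
        else:
            pieces = [trim_record(record, target_duration)]
        out.extend(decimate(p, target_rate) for p in pieces)
    return out


def prepare_dataset(
    manifest: pd.DataFrame,
    catalog: ActivityCatalog,
    target_rate: float,
    conversion: ConversionConfig | None = None,
    source_rate: float = 200.0,
    target_duration: float = TARGET_DURATION_S,
    window_offsets: Sequence[float] = DEFAULT_WINDOW_OFFSETS,
) -> list[IMURecord]:
    """Read every manifest row and run the full preprocessing chain on it."""

    def _iter():
        for row in manifest.itertuples(index=False):
            try:
                yield read_sisfall_record(
                    Path(row.path), catalog, conversion, sampling_rate=source_rate
                )
            except Exception as exc:
                raise RuntimeError(f"failed to preprocess {row.path}") from exc

    return prepare_records(
        _iter(), catalog, target_rate, target_duration, window_offsets
    )
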