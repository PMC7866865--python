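"""The 88-dimensional time/frequency feature vector and min-max scaling.

Eleven feature classes are computed on each of eight channels: the three
accelerometer axes, the three gyroscope axes, and the Euclidean magnitude of
each sensor.  Nine classes are time-domain statistics (population variance,
standard deviation, mean, median, maximum, minimum, delta = peak-to-peak,
25th and 75th centiles); two are frequency-domain, computed from the
one-sided periodogram: its mean power (spectral density) and its Shannon
entropy in bits (spectral entropy).

The vector is laid out channel-major — all eleven classes of ``accel_x``
first, then ``accel_y``, ... ending with ``gyro_magnitude`` — and the order
is fixed; :func:`feature_names` is the canonical column list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .core import IMURecord

CHANNELS = (
    "accel_x",
    "accel_y",
    "accel_z",
    "accel_magnitude",
    "gyro_x",
    "gyro_y",
    "gyro_z",
    "gyro_magnitude",
)

TIME_FEATURE_CLASSES = (
    "variance",
    "std",
    "mean",
    "median",
    "max",
    "min",
    "delta",
    "p25",
    "p75",
)

FREQ_FEATURE_CLASSES = ("spectral_density", "spectral_entropy")

FEATURE_CLASSES = TIME_FEATURE_CLASSES + FREQ_FEATURE_CLASSES

#: Metadata columns attached to every feature row.
META_COLUMNS = ("label", "subject", "activity", "trial", "phase")


def feature_names() -> list[str]:
    """The 88 feature column names, channel-major, in canonical order."""
    return [f"{ch}__{feat}" for ch in CHANNELS for feat in FEATURE_CLASSES]


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of three equal-length axis series."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis series must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def time_features(s: np.ndarray) -> np.ndarray:
    """Nine time-domain statistics of a series (population variance)."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    mx = float(np.max(s))
    mn = float(np.min(s))
    return np.array(
        [
            float(np.var(s)),
            float(np.std(s)),
            float(np.mean(s)),
            float(np.median(s)),
            mx,
            mn,
            mx - mn,
            float(np.percentile(s, 25)),
            float(np.percentile(s, 75)),
        ]
    )


def periodogram(s: np.ndarray) -> np.ndarray:
    """One-sided power spectrum P_k = |FFT(s)_k|^2 / N, k = 0..floor(N/2)."""
    s = np.asarray(s, dtype=float)
    return np.abs(np.fft.rfft(s)) ** 2 / s.size


def freq_features(s: np.ndarray) -> np.ndarray:
    """Mean one-sided periodogram power and its spectral entropy in bits.

    The DC bin is included.  An all-zero spectrum has entropy 0 by the
    convention 0*log(0) = 0.
    """
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ValueError("series must have at least 2 samples")
    p = periodogram(s)
    total = p.sum()
    psd = float(p.mean())
    if total <= 0:
        return np.array([psd, 0.0])
    q = p / total
    nz = q[q > 0]
    pse = float(-(nz * np.log2(nz)).sum())
    return np.array([psd, pse])


def channel_matrix(record: IMURecord) -> np.ndarray:
    """Stack the eight channels of a record as an (n_samples, 8) matrix."""
    acc_mag = magnitude(record.accel[:, 0], record.accel[:, 1], record.accel[:, 2])
    gyr_mag = magnitude(record.gyro[:, 0], record.gyro[:, 1], record.gyro[:, 2])
    return np.column_stack(
        [record.accel, acc_mag[:, None], record.gyro, gyr_mag[:, None]]
    )


@dataclass
class FeatureVector:
    """An 88-value descriptor of one record or phase segment."""

    values: np.ndarray
    label: str
    subject_id: str
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(CHANNELS) * len(FEATURE_CLASSES),):
            raise ValueError(f"expected 88 values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def build_feature_vector(
    record: IMURecord, label: str | None = None, phase: str = "full"
) -> FeatureVector:
    """Compute the 88-dimensional feature vector of a record (or segment)."""
    mat = channel_matrix(record)
    values = np.empty(len(CHANNELS) * len(FEATURE_CLASSES))
    k = len(FEATURE_CLASSES)
    for c in range(mat.shape[1]):
        col = mat[:, c]
        values[c * k : c * k + 9] = time_features(col)
        values[c * k + 9 : c * k + 11] = freq_features(col)
    return FeatureVector(
        values=values,
        label=label if label is not None else record.label,
        subject_id=record.subject_id,
        provenance={
            "activity_code": record.activity_code,
            "trial": record.trial_index,
            "phase": phase,
        },
    )


def extract_features(records, labels=None, phases=None) -> pd.DataFrame:
    """Feature matrix for a list of records.

    Returns a DataFrame whose first 88 columns are the canonical feature
    names, followed by ``label, subject, activity, trial, phase`` metadata.
    """
    names = feature_names()
    rows = []
    meta = []
    for i, record in enumerate(records):
        label = labels[i] if labels is not None else record.label
        phase = phases[i] if phases is not None else "full"
        fv = build_feature_vector(record, label=label, phase=phase)
        rows.append(fv.values)
        meta.append(
            (
                fv.label,
                fv.subject_id,
                fv.provenance["activity_code"],
                fv.provenance["trial"],
                fv.provenance["phase"],
            )
        )
    frame = pd.DataFrame(np.asarray(rows), columns=names)
    frame[list(META_COLUMNS)] = pd.DataFrame(meta, columns=list(META_COLUMNS))
    return frame


def minmax_fit(train_matrix: np.ndarray) -> MinMaxScaler:
    """Fit a per-column min-max scaler on the training matrix.

    Scaled training values lie in [0, 1]; constant columns map to 0.  Test
    values outside the training range are NOT clipped.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.ndim != 2 or train_matrix.shape[0] < 1:
        raise ValueError("fit requires a 2-D matrix with at least one row")
    return MinMaxScaler(clip=False).fit(train_matrix)


def minmax_apply(scaler: MinMaxScaler, matrix: np.ndarray) -> np.ndarray:
    """Apply a fitted min-max scaler; raises if the scaler is unfitted."""
    return scaler.transform(np.asarray(matrix, dtype=float))
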