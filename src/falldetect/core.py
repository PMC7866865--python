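"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`IMURecord`: one trial's worth of synchronous
tri-axial accelerometer and tri-axial gyroscope samples, together with the
metadata needed to trace it back to a subject, an activity and a trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Label = Literal["ADL", "FALL"]

#: The four classes of the fall-phase classification task, in canonical order.
PHASE_CLASSES = ("ADL", "PRE_FALL", "IMPACT", "POST_FALL")


@dataclass
class IMURecord:
    """One trial of waist-worn IMU data.

    Parameters
    ----------
    subject_id : str
        Cohort subject identifier, e.g. ``"SA01"``.
    activity_code : str
        Activity code, e.g. ``"D01"`` (ADL) or ``"F05"`` (fall).
    trial_index : int
        1-based trial number within (subject, activity).
    sampling_rate : float
        Sampling rate in Hz; identical for all six channels.
    accel : ndarray, shape (n_samples, 3)
        Acceleration in g, axis order x, y, z.
    gyro : ndarray, shape (n_samples, 3)
        Angular velocity in deg/s, axis order x, y, z.
    label : {"ADL", "FALL"}
        Binary ground-truth class of the whole trial.
    """

    subject_id: str
    activity_code: str
    trial_index: int
    sampling_rate: float
    accel: np.ndarray
    gyro: np.ndarray
    label: Label
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError(f"accel must have shape (n, 3), got {self.accel.shape}")
        if self.gyro.shape != self.accel.shape:
            raise ValueError(
                f"gyro shape {self.gyro.shape} != accel shape {self.accel.shape}"
            )
        if self.accel.shape[0] < 1:
            raise ValueError("record must contain at least one sample")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.trial_index < 1:
            raise ValueError("trial_index must be a positive integer")
        if self.label not in ("ADL", "FALL"):
            raise ValueError(f"label must be ADL or FALL, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration(self) -> float:
        """Record duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def slice(self, start: int, stop: int) -> "IMURecord":
        """Return the half-open sample interval [start, stop) as a new record."""
        if not (0 <= start < stop <= self.n_samples):
            raise ValueError(
                f"invalid slice [{start}, {stop}) for {self.n_samples} samples"
            )
        return replace(self, accel=self.accel[start:stop], gyro=self.gyro[start:stop])

    def with_(self, **changes) -> "IMURecord":
        return replace(self, **changes)
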