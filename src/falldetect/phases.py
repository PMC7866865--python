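"""Fall-phase segmentation: impact localization and the 4-class dataset.

A fall record is split at its impact point — the sample where the
accelerometer magnitude attains its global maximum — into three phases:
a 2-s impact window (1.5 s before the impact point, 0.5 s after), the
pre-fall phase before that window, and the post-fall phase after it.
With ADL records kept whole, the task becomes four-class classification
over {ADL, PRE_FALL, IMPACT, POST_FALL}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IMURecord, PHASE_CLASSES
from .features import extract_features, magnitude

logger = logging.getLogger(__name__)

PRE_LEAD_S = 1.5
POST_LAG_S = 0.5


@dataclass(frozen=True)
class PhaseSegments:
    """Half-open sample intervals of the three fall phases.

    The intervals are disjoint, ordered, and partition [0, n_samples);
    pre-fall and/or post-fall may be empty when the impact sits near a
    record boundary, in which case the impact window is clamped.
    """

    pre_fall: tuple[int, int]
    impact: tuple[int, int]
    post_fall: tuple[int, int]
    impact_index: int
    sampling_rate: float

    def __post_init__(self) -> None:
        a, b = self.impact
        if not (self.pre_fall[1] == a and b == self.post_fall[0]):
            raise ValueError("phase intervals must be contiguous")
        if not a <= self.impact_index < b:
            raise ValueError("impact_index must lie inside the impact interval")

    @property
    def n_samples(self) -> int:
        return self.post_fall[1]

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {
            "PRE_FALL": self.pre_fall,
            "IMPACT": self.impact,
            "POST_FALL": self.post_fall,
        }


def find_impact(record: IMURecord) -> int:
    """Index of the global accelerometer-magnitude maximum (earliest on ties)."""
    mag = magnitude(record.accel[:, 0], record.accel[:, 1], record.accel[:, 2])
    return int(np.argmax(mag))


def segment_phases(
    record: IMURecord,
    impact_index: int,
    pre_lead: float = PRE_LEAD_S,
    post_lag: float = POST_LAG_S,
) -> PhaseSegments:
    """Partition a record into pre-fall / impact / post-fall around the impact.

    The impact window is ``[impact_index - round(pre_lead * rate),
    impact_index + round(post_lag * rate))`` intersected with the record;
    unclamped it spans exactly ``pre_lead + post_lag`` seconds.
    """
    n = record.n_samples
    if not 0 <= impact_index < n:
        raise ValueError(f"impact_index {impact_index} outside record of {n} samples")
    rate = record.sampling_rate
    start = max(0, impact_index - int(round(pre_lead * rate)))
    stop = min(n, impact_index + int(round(post_lag * rate)))
    return PhaseSegments(
        pre_fall=(0, start),
        impact=(start, stop),
        post_fall=(stop, n),
        impact_index=impact_index,
        sampling_rate=rate,
    )


def build_multiclass_dataset(
    records: list[IMURecord],
    pre_lead: float = PRE_LEAD_S,
    post_lag: float = POST_LAG_S,
) -> tuple[pd.DataFrame, dict]:
    """Build the 4-class feature dataset from uniform-rate records.

    Each ADL record contributes one feature vector labeled ``ADL``; each
    fall record contributes up to three vectors labeled ``PRE_FALL``,
    ``IMPACT`` and ``POST_FALL``.  Phases emptied by boundary clamping are
    skipped and counted in the returned report.

    Returns ``(features, report)`` where ``features`` has the 88 feature
    columns plus metadata, with the class in the ``phase`` column, and
    ``report`` counts records and skipped empty phases.
    """
    if not records:
        raise ValueError("no records supplied")
    rates = {r.sampling_rate for r in records}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates {sorted(rates)}; decimate first")
    durations = {r.n_samples for r in records}
    if len(durations) > 1:
        raise ValueError("records must have uniform length; preprocess first")

    segments: list[IMURecord] = []
    phase_labels: list[str] = []
    report = {"n_adl": 0, "n_fall": 0, "empty_phases": 0}
    for record in records:
        if record.label == "ADL":
            report["n_adl"] += 1
            segments.append(record)
            phase_labels.append("ADL")
            continue
        report["n_fall"] += 1
        seg = segment_phases(record, find_impact(record), pre_lead, post_lag)
        for phase, (a, b) in seg.as_dict().items():
            if a == b:
                report["empty_phases"] += 1
                logger.warning(
                    "empty %s phase in %s/%s trial %d (impact at sample %d)",
                    phase,
                    record.subject_id,
                    record.activity_code,
                    record.trial_index,
                    seg.impact_index,
                )
                continue
            segments.append(record.slice(a, b))
            phase_labels.append(phase)

    frame = extract_features(segments, phases=phase_labels)
    frame["phase"] = pd.Categorical(
        frame["phase"], categories=list(PHASE_CLASSES), ordered=True
    )
    return frame, report
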