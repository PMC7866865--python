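"""Synthetic SisFall-shaped cohorts with known ground truth.

The generator emulates the statistical structure the pipeline relies on,
not fall biomechanics: ADLs are periodic gait signals or smooth posture
transitions riding on a 1-g gravity offset, and falls are a quiet pre-fall
baseline, a single dominant acceleration transient of known center time,
and a changed lying posture afterwards.  Every record is reproducible in
isolation: the per-record random stream is derived from the cohort seed and
the (subject, activity, trial) coordinates, so generation order never
affects the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import IMURecord
from .io import ActivityCatalog, ConversionConfig, scan_manifest, write_sisfall_record

#: Profile kind per SisFall ADL code; long walking/jogging records and the
#: stair activities are gait-like, everything else is a posture transition.
ADL_KIND_MAP = {
    "D01": "gait", "D02": "gait", "D03": "gait", "D04": "gait",
    "D05": "gait", "D06": "gait", "D18": "gait",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generation parameters.

    Defaults mirror the filtered SisFall design: 20 subjects, five trials
    per activity (one per long walking/jogging record), 200 Hz sampling.
    Amplitudes are in g: sensor noise of 0.05 g, a 6-g impact transient,
    and impact times drawn uniformly in ``impact_time_bounds`` so that the
    peak stays interior after trimming to 10 s.
    """

    n_subjects: int = 20
    trials_per_activity: int = 5
    sampling_rate: float = 200.0
    noise_sd: float = 0.05
    fall_peak: float = 6.0
    impact_time_bounds: tuple[float, float] = (5.0, 10.0)
    gait_amplitude: float = 0.4
    gyro_noise_sd: float = 2.0
    gyro_pulse: float = 250.0
    gravity_axis: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fall_peak <= 3 * self.noise_sd:
            raise ValueError(
                "fall_peak must exceed 3 * noise_sd so impacts dominate noise"
            )
        if not 0 <= self.gravity_axis <= 2:
            raise ValueError("gravity_axis must be 0, 1 or 2")

    def record_rng(self, *coords: int) -> np.random.Generator:
        """Deterministic per-record substream keyed by integer coordinates."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.rng_seed), *map(int, coords)])
        )


def _gravity(config: SyntheticConfig, n: int, axis: int | None = None) -> np.ndarray:
    g = np.zeros((n, 3))
    g[:, config.gravity_axis if axis is None else axis] = 1.0
    return g


def _smoothstep(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """C1 ramp from 0 to 1 over [center - width/2, center + width/2]."""
    x = np.clip((t - center) / width + 0.5, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _noise(rng, n: int, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, size=(n, 3)) if sd > 0 else np.zeros((n, 3))


def gen_adl(
    kind: str,
    duration: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    subject_id: str = "S01",
    activity_code: str = "D01",
    trial_index: int = 1,
) -> IMURecord:
    """Generate one ADL trial of the given profile kind.

    ``gait``: sinusoidal acceleration components plus the 1-g gravity offset;
    ``transition``: a smooth ramp between two posture orientations and back;
    ``static``: gravity plus noise only.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    accel = _gravity(config, n)
    gyro = np.zeros((n, 3))

    if kind == "gait":
        freq = rng.uniform(1.5, 2.8)
        amp = config.gait_amplitude * rng.uniform(0.8, 1.2)
        phase = rng.uniform(0, 2 * np.pi)
        vert = config.gravity_axis
        fwd = (vert + 1) % 3
        lat = (vert + 2) % 3
        accel[:, vert] += amp * np.sin(2 * np.pi * freq * t + phase)
        accel[:, fwd] += 0.6 * amp * np.sin(2 * np.pi * freq * t + phase + np.pi / 3)
        accel[:, lat] += 0.2 * amp * np.sin(2 * np.pi * 0.5 * freq * t + phase)
        gyro[:, lat] += 40.0 * np.sin(2 * np.pi * freq * t + phase)
        gyro[:, vert] += 15.0 * np.sin(2 * np.pi * freq * t + phase + np.pi / 2)
    elif kind == "transition":
        # posture A -> tilted posture B -> back to A (e.g. sit down, get up)
        vert = config.gravity_axis
        other = (vert + 1) % 3
        tilt = rng.uniform(0.4, 0.8)
        t1 = duration * rng.uniform(0.25, 0.4)
        t2 = duration * rng.uniform(0.6, 0.75)
        width = rng.uniform(1.0, 2.0)
        ramp = _smoothstep(t, t1, width) - _smoothstep(t, t2, width)
        accel[:, vert] += tilt * (np.cos(np.pi / 4) - 1.0) * ramp
        accel[:, other] += tilt * np.sin(np.pi / 4) * ramp
        dramp = np.gradient(ramp, t)
        gyro[:, (vert + 2) % 3] += 60.0 * dramp
    elif kind == "static":
        pass
    else:
        raise ValueError(f"unknown ADL kind {kind!r}")

    accel += _noise(rng, n, config.noise_sd)
    gyro += _noise(rng, n, config.gyro_noise_sd)
    return IMURecord(
        subject_id=subject_id,
        activity_code=activity_code,
        trial_index=trial_index,
        sampling_rate=config.sampling_rate,
        accel=accel,
        gyro=gyro,
        label="ADL",
        meta={"kind": kind},
    )


def gen_fall(
    duration: float,
    impact_time: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    subject_id: str = "S01",
    activity_code: str = "F01",
    trial_index: int = 1,
) -> IMURecord:
    """Generate one fall trial whose accelerometer-magnitude maximum sits at
    ``impact_time`` (within one sample).

    The record is a standing baseline with mild sway, a Gaussian transient of
    amplitude ``config.fall_peak`` centered at the impact, a correlated
    angular-rate pulse on the gyroscope, and a lying posture afterwards.
    The ground-truth impact time is stored in ``record.meta["impact_time_s"]``.
    """
    if not 0 < impact_time < duration:
        raise ValueError(
            f"impact_time {impact_time} outside record duration {duration}"
        )
    n = int(round(duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    vert = config.gravity_axis
    fwd = (vert + 1) % 3
    lying_axis = (vert + 2) % 3

    # standing baseline with mild sway, blending into a lying posture shortly
    # after the impact
    blend = _smoothstep(t, impact_time + 0.4, 0.6)
    accel = (1.0 - blend)[:, None] * _gravity(config, n)
    accel += blend[:, None] * _gravity(config, n, axis=lying_axis)
    sway = 0.1 * np.sin(2 * np.pi * 1.5 * t + rng.uniform(0, 2 * np.pi))
    accel[:, vert] += (1.0 - blend) * sway

    # impact transient: narrow Gaussian bump, mostly vertical
    sigma = 0.06
    bump = np.exp(-0.5 * ((t - impact_time) / sigma) ** 2)
    accel[:, vert] += config.fall_peak * bump
    accel[:, fwd] += 0.3 * config.fall_peak * bump

    gyro = np.zeros((n, 3))
    gyro[:, lying_axis] += config.gyro_pulse * np.exp(
        -0.5 * ((t - impact_time) / (2 * sigma)) ** 2
    )

    accel += _noise(rng, n, config.noise_sd)
    gyro += _noise(rng, n, config.gyro_noise_sd)
    return IMURecord(
        subject_id=subject_id,
        activity_code=activity_code,
        trial_index=trial_index,
        sampling_rate=config.sampling_rate,
        accel=accel,
        gyro=gyro,
        label="FALL",
        meta={"impact_time_s": float(impact_time)},
    )


def _activity_kind(code: str, info) -> str:
    return ADL_KIND_MAP.get(code, "gait" if info.long_record else "transition")


def iter_cohort_records(config: SyntheticConfig, catalog: ActivityCatalog):
    """Yield every record of the cohort, lazily, in deterministic order.

    Long-record activities get a single trial (they are window-expanded by
    preprocessing into five 10-s sub-trials); all others get
    ``config.trials_per_activity`` trials.
    """
    codes = catalog.codes
    for si in range(config.n_subjects):
        subject = f"SA{si + 1:02d}"
        for ai, code in enumerate(codes):
            info = catalog[code]
            n_trials = 1 if info.long_record else config.trials_per_activity
            for trial in range(1, n_trials + 1):
                rng = config.record_rng(si, ai, trial)
                if info.label == "FALL":
                    impact = rng.uniform(*config.impact_time_bounds)
                    yield gen_fall(
                        info.nominal_duration,
                        impact,
                        config,
                        rng,
                        subject_id=subject,
                        activity_code=code,
                        trial_index=trial,
                    )
                else:
                    yield gen_adl(
                        _activity_kind(code, info),
                        info.nominal_duration,
                        config,
                        rng,
                        subject_id=subject,
                        activity_code=code,
                        trial_index=trial,
                    )


def gen_cohort(
    config: SyntheticConfig,
    catalog: ActivityCatalog,
    out_dir,
    conversion: ConversionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a full synthetic cohort as SisFall-dialect files.

    Returns ``(manifest, ground_truth)`` where the ground-truth sidecar has
    one row per fall file with its true impact time in seconds.  The sidecar
    is also written to ``out_dir / "ground_truth.csv"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conversion = conversion or ConversionConfig()
    truth_rows = []
    for record in iter_cohort_records(config, catalog):
        subj_dir = out_dir / record.subject_id
        subj_dir.mkdir(exist_ok=True)
        name = f"{record.activity_code}_{record.subject_id}_R{record.trial_index:02d}.txt"
        path = subj_dir / name
        write_sisfall_record(record, path, conversion)
        if record.label == "FALL":
            truth_rows.append(
                {"path": str(path), "impact_time_s": record.meta["impact_time_s"]}
            )
    truth = pd.DataFrame(truth_rows, columns=["path", "impact_time_s"])
    manifest = scan_manifest(out_dir, catalog)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth
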