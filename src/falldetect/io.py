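"""Reading and writing SisFall-dialect trial files and cohort manifests.

A trial file holds one sample per line: nine comma-separated integer sensor
counts (first accelerometer x,y,z; gyroscope x,y,z; second accelerometer
x,y,z), optionally terminated by a semicolon.  Only the first accelerometer
and the gyroscope are used; the trailing three columns are discarded on read.

Raw counts are converted to physical units with the linear map

    value = counts * (2 * full_range / 2**resolution_bits)

using the sensor's full range (+-range) and ADC resolution.  The shipped
defaults (+-16 g / 13 bit for the accelerometer, +-2000 deg/s / 16 bit for
the gyroscope) come from the ADXL345 and ITG3200 datasheets and can be
overridden, including an identity conversion that keeps raw counts.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import IMURecord

logger = logging.getLogger(__name__)

#: Default filename convention: "<activity>_<subject>_R<trial>", e.g. D01_SA05_R03.txt
FILENAME_PATTERN = re.compile(
    r"^(?P<activity>[A-Za-z]\d{2})_(?P<subject>[A-Za-z0-9]+)_R(?P<trial>\d+)$"
)

MANIFEST_COLUMNS = ["path", "subject", "activity", "trial", "label"]


class ParseError(ValueError):
    """A trial file line could not be parsed."""


class CatalogError(KeyError):
    """An activity code is missing from the catalog."""


def raw_to_physical(
    counts: np.ndarray, full_range: float, resolution_bits: int
) -> np.ndarray:
    """Convert integer sensor counts to physical units.

    The conversion is linear and sign-preserving:
    ``value = counts * (2 * full_range / 2**resolution_bits)``.
    """
    if resolution_bits < 1:
        raise ValueError("resolution_bits must be >= 1")
    if full_range <= 0:
        raise ValueError("full_range must be positive")
    scale = 2.0 * full_range / (2**resolution_bits)
    return np.asarray(counts, dtype=float) * scale


def physical_to_raw(
    values: np.ndarray, full_range: float, resolution_bits: int
) -> np.ndarray:
    """Inverse of :func:`raw_to_physical`; rounds to the nearest count."""
    scale = 2.0 * full_range / (2**resolution_bits)
    return np.rint(np.asarray(values, dtype=float) / scale).astype(np.int64)


@dataclass(frozen=True)
class ConversionConfig:
    """Count-to-physical conversion constants for the two used sensors.

    ``identity()`` disables conversion so downstream code sees raw counts;
    useful for exactness tests and for replicating raw-count pipelines.
    """

    accel_range_g: float = 16.0
    accel_bits: int = 13
    gyro_range_dps: float = 2000.0
    gyro_bits: int = 16
    identity_mode: bool = False

    @classmethod
    def identity(cls) -> "ConversionConfig":
        return cls(identity_mode=True)

    def accel_from_counts(self, counts: np.ndarray) -> np.ndarray:
        if self.identity_mode:
            return np.asarray(counts, dtype=float)
        return raw_to_physical(counts, self.accel_range_g, self.accel_bits)

    def gyro_from_counts(self, counts: np.ndarray) -> np.ndarray:
        if self.identity_mode:
            return np.asarray(counts, dtype=float)
        return raw_to_physical(counts, self.gyro_range_dps, self.gyro_bits)

    def accel_to_counts(self, values: np.ndarray) -> np.ndarray:
        if self.identity_mode:
            return np.rint(np.asarray(values)).astype(np.int64)
        return physical_to_raw(values, self.accel_range_g, self.accel_bits)

    def gyro_to_counts(self, values: np.ndarray) -> np.ndarray:
        if self.identity_mode:
            return np.rint(np.asarray(values)).astype(np.int64)
        return physical_to_raw(values, self.gyro_range_dps, self.gyro_bits)


@dataclass(frozen=True)
class ActivityInfo:
    code: str
    label: str
    name: str
    nominal_duration: float
    long_record: bool


class ActivityCatalog:
    """Mapping from activity code to label, nominal duration and record kind.

    The packaged default mirrors the SisFall protocol: 19 ADLs and 15 fall
    types, of which exactly the four walking/jogging ADLs are single-trial
    100-s "long" records.
    """

    def __init__(self, entries: dict[str, ActivityInfo]):
        if not entries:
            raise ValueError("catalog must contain at least one activity")
        self._entries = dict(entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def codes(self) -> list[str]:
        return sorted(self._entries)

    @property
    def adl_codes(self) -> list[str]:
        return [c for c in self.codes if self._entries[c].label == "ADL"]

    @property
    def fall_codes(self) -> list[str]:
        return [c for c in self.codes if self._entries[c].label == "FALL"]

    def __getitem__(self, code: str) -> ActivityInfo:
        try:
            return self._entries[code]
        except KeyError:
            raise CatalogError(f"unknown activity code {code!r}") from None

    @classmethod
    def from_yaml(cls, path_or_stream) -> "ActivityCatalog":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            raw = yaml.safe_load(Path(path_or_stream).read_text())
        entries = {
            code: ActivityInfo(
                code=code,
                label=spec["label"],
                name=spec.get("name", code),
                nominal_duration=float(spec["nominal_duration"]),
                long_record=bool(spec.get("long_record", False)),
            )
            for code, spec in raw["activities"].items()
        }
        return cls(entries)

    @classmethod
    def default(cls) -> "ActivityCatalog":
        ref = resources.files("falldetect.data") / "sisfall_catalog.yaml"
        with ref.open("r") as fh:
            return cls.from_yaml(fh)


def parse_trial_filename(
    name: str, pattern: re.Pattern = FILENAME_PATTERN
) -> tuple[str, str, int] | None:
    """Parse ``<activity>_<subject>_R<trial>`` from a file stem.

    Returns ``(activity_code, subject_id, trial_index)`` or None when the
    name does not follow the convention.
    """
    m = pattern.match(Path(name).stem)
    if m is None:
        return None
    return m.group("activity"), m.group("subject"), int(m.group("trial"))


def _parse_counts(path: Path) -> np.ndarray:
    """Parse a trial file into an (n, 9) integer count array.

    Fast path via the pandas C tokenizer; on failure, a line-by-line pass
    locates the offending line so errors carry a 1-based line number.
    """
    text = Path(path).read_text()
    cleaned = text.replace(";", "")
    try:
        frame = pd.read_csv(
            _io.StringIO(cleaned),
            header=None,
            sep=",",
            skip_blank_lines=True,
            dtype=np.int64,
        )
        if frame.shape[1] != 9:
            raise ValueError(f"expected 9 columns, found {frame.shape[1]}")
        return frame.to_numpy()
    except (ValueError, pd.errors.ParserError):
        pass
    # diagnostic pass
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip().rstrip(";").strip()
        if not stripped:
            continue
        fields = [f.strip() for f in stripped.split(",")]
        if len(fields) != 9:
            raise ParseError(
                f"{path}: line {lineno}: expected 9 comma-separated fields, "
                f"got {len(fields)}"
            )
        try:
            rows.append([int(f) for f in fields])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric field in {stripped!r}"
            ) from None
    if not rows:
        raise ParseError(f"{path}: file contains no samples")
    return np.asarray(rows, dtype=np.int64)


def read_sisfall_record(
    path,
    catalog: ActivityCatalog,
    conversion: ConversionConfig | None = None,
    sampling_rate: float = 200.0,
    filename_pattern: re.Pattern = FILENAME_PATTERN,
) -> IMURecord:
    """Read one SisFall-dialect trial file into an :class:`IMURecord`.

    Columns 1-3 (first accelerometer) and 4-6 (gyroscope) are converted to
    physical units; columns 7-9 (second accelerometer) are discarded.  The
    binary label comes from the catalog entry for the activity code parsed
    from the filename.
    """
    path = Path(path)
    conversion = conversion or ConversionConfig()
    parsed = parse_trial_filename(path.name, filename_pattern)
    if parsed is None:
        raise ParseError(f"cannot parse activity/subject/trial from {path.name!r}")
    activity, subject, trial = parsed
    info = catalog[activity]
    counts = _parse_counts(path)
    return IMURecord(
        subject_id=subject,
        activity_code=activity,
        trial_index=trial,
        sampling_rate=sampling_rate,
        accel=conversion.accel_from_counts(counts[:, 0:3]),
        gyro=conversion.gyro_from_counts(counts[:, 3:6]),
        label=info.label,
        meta={"path": str(path)},
    )


def write_sisfall_record(
    record: IMURecord, path, conversion: ConversionConfig | None = None
) -> Path:
    """Write a record in the SisFall text dialect (semicolon-terminated lines).

    The unused second-accelerometer columns are written as zeros.
    """
    path = Path(path)
    conversion = conversion or ConversionConfig()
    acc = conversion.accel_to_counts(record.accel)
    gyr = conversion.gyro_to_counts(record.gyro)
    zeros = np.zeros((record.n_samples, 3), dtype=np.int64)
    counts = np.hstack([acc, gyr, zeros])
    body = pd.DataFrame(counts).to_csv(header=False, index=False, lineterminator=";\n")
    path.write_text(body)
    return path


def scan_manifest(
    root,
    catalog: ActivityCatalog,
    filename_pattern: re.Pattern = FILENAME_PATTERN,
) -> pd.DataFrame:
    """Scan a directory tree for trial files and build a cohort manifest.

    Returns a DataFrame with columns ``path, subject, activity, trial, label``
    ordered lexicographically by path.  Files whose names do not follow the
    convention, or whose activity code is not in the catalog, are skipped
    with a logged warning; the skip count is stored in ``df.attrs["skipped"]``.
    """
    root = Path(root)
    rows = []
    skipped = 0
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        parsed = parse_trial_filename(path.name, filename_pattern)
        if parsed is None:
            logger.warning("skipping unrecognized file %s", path)
            skipped += 1
            continue
        activity, subject, trial = parsed
        if activity not in catalog:
            logger.warning("skipping %s: activity %r not in catalog", path, activity)
            skipped += 1
            continue
        rows.append(
            {
                "path": str(path),
                "subject": subject,
                "activity": activity,
                "trial": trial,
                "label": catalog[activity].label,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    dupes = manifest.duplicated(subset=["subject", "activity", "trial"])
    if dupes.any():
        raise ValueError(
            f"duplicate (subject, activity, trial) triples in manifest: "
            f"{manifest.loc[dupes, 'path'].tolist()[:5]}"
        )
    manifest.attrs["skipped"] = skipped
    if skipped:
        logger.warning("manifest scan skipped %d unrecognized files", skipped)
    return manifest


def write_manifest(manifest: pd.DataFrame, path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return frame[MANIFEST_COLUMNS]
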