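"""Generate a small SisFall-shaped synthetic cohort and inspect it.

Writes trial files in the SisFall text dialect (nine comma-separated integer
counts per line), scans them back into a manifest, and shows the cohort
arithmetic: every short activity has five trials, the four 100-s
walking/jogging records have one trial each (they are window-expanded later).
"""

import tempfile
from pathlib import Path

import falldetect as fd

catalog = fd.ActivityCatalog.default()
config = fd.SyntheticConfig(n_subjects=2, rng_seed=42)

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "cohort"
    manifest, truth = fd.gen_cohort(config, catalog, root)

    print(f"trial files written : {len(manifest)}")
    print(f"  ADL files         : {(manifest['label'] == 'ADL').sum()}")
    print(f"  fall files        : {(manifest['label'] == 'FALL').sum()}")
    print(f"fall ground truths  : {len(truth)} (impact times in seconds)")
    print(truth.head(3).to_string(index=False))

    rec = fd.read_sisfall_record(manifest["path"].iloc[0], catalog)
    print(
        f"\nfirst record: {rec.activity_code} subject {rec.subject_id}, "
        f"{rec.n_samples} samples at {rec.sampling_rate:.0f} Hz "
        f"({rec.duration:.0f} s), label {rec.label}"
    )

# With 2 subjects: 2 x (30 short activities x 5 trials + 4 long x 1) = 308
# files; after window expansion the cohort yields 2 x 170 = 340 records.
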