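import numpy as np
import pytest

import falldetect as fd


@pytest.fixture(scope="session")
def catalog():
    return fd.ActivityCatalog.default()


@pytest.fixture(scope="session")
def small_config():
    """A 5-subject cohort config, large enough for 5-fold subject CV."""
    return fd.SyntheticConfig(n_subjects=5, rng_seed=123)


@pytest.fixture(scope="session")
def small_records(small_config, catalog):
    return list(fd.iter_cohort_records(small_config, catalog))


@pytest.fixture(scope="session")
def prepared50(small_records, catalog):
    """The small cohort trimmed/window-expanded and decimated to 50 Hz."""
    return fd.prepare_records(small_records, catalog, 50.0)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, catalog):
    """A 2-subject cohort written to disk in the SisFall dialect."""
    root = tmp_path_factory.mktemp("cohort")
    cfg = fd.SyntheticConfig(n_subjects=2, rng_seed=321)
    manifest, truth = fd.gen_cohort(cfg, catalog, root)
    return root, manifest, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def fall_record():
    """One noiseless 10-s fall at 50 Hz with the impact at exactly 5.0 s."""
    cfg = fd.SyntheticConfig(sampling_rate=50.0, noise_sd=0.0, rng_seed=0)
    return fd.gen_fall(10.0, 5.0, cfg, np.random.default_rng(0))
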