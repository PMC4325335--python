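import numpy as np
import pytest

import duoscan as ds


@pytest.fixture(scope="session")
def small_site() -> ds.SiteConfig:
    """A desk-scale acquisition geometry (20x20x10 voxels, TR 2 s)."""
    return ds.SiteConfig("A", tr_seconds=2.0, n_slices=10, matrix_size=(20, 20),
                         field_label="3T")


@pytest.fixture(scope="session")
def noiseless_subject() -> ds.SubjectProfile:
    """Subject with the reference maximal amplitude and no noise or drift."""
    return ds.SubjectProfile(
        "subj01", max_amplitude_percent=2.69, activation_center=(10, 10, 5),
        activation_radius=3.0, noise_sd_percent=0.0, drift_amplitude_percent=0.0,
    )


@pytest.fixture(scope="session")
def localizer() -> ds.BlockDesign:
    return ds.localizer_design()


@pytest.fixture(scope="session")
def noiseless_localizer_series(localizer, noiseless_subject, small_site):
    return ds.simulate_run(
        localizer, noiseless_subject, small_site,
        np.ones(localizer.n_blocks), seed=11,
    )


@pytest.fixture(scope="session")
def center_roi(small_site):
    from duoscan.analysis import RoiMask

    mask = np.zeros(small_site.volume_shape, dtype=bool)
    mask[10, 10, 5] = True
    return RoiMask(mask, provenance={"note": "blob-centre voxel"})
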