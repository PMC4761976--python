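"""Shared fixtures: small deterministic grids, atlases and cohorts."""
import numpy as np
import pytest

import seedconn as sc

# Reduced acquisition used by the Monte-Carlo suites: full-length
# timecourse (the temporal statistics under test are unchanged) on a
# smaller spatial grid.
SCALED = sc.AcquisitionSpec(nx=40, ny=40, nz=7, n_volumes=300)

# Tiny acquisition for fast unit/integration tests.
TINY = sc.AcquisitionSpec(nx=24, ny=24, nz=5, n_volumes=80)


@pytest.fixture(scope="session")
def scaled_spec():
    return SCALED


@pytest.fixture(scope="session")
def scaled_atlas():
    return sc.make_toy_atlas(SCALED, n_rois=25)


@pytest.fixture(scope="session")
def tiny_spec():
    return TINY


@pytest.fixture(scope="session")
def tiny_atlas():
    return sc.make_toy_atlas(TINY, n_rois=8)


@pytest.fixture(scope="session")
def scaled_subject(scaled_atlas):
    """One preprocessed SHR-like subject on the reduced grid."""
    truth = sc.build_target_matrix(scaled_atlas, sc.shr_like_profile())
    img = sc.simulate_subject(truth, subject_seed=12345)
    proc, mask = sc.preprocess_subject(img)
    return truth, img, proc, mask


def maps_from_z(z_stack, valid=None):
    """Build SubjectCorrMap objects from an (n_subjects, ...) z array."""
    z_stack = np.asarray(z_stack, dtype=np.float64)
    maps = []
    for i, z in enumerate(z_stack):
        v = np.ones(z.shape, dtype=bool) if valid is None else valid[i]
        maps.append(
            sc.SubjectCorrMap(
                r_map=np.tanh(z), z_map=z, valid_mask=v, subject_id=f"s{i}"
            )
        )
    return maps
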