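import numpy as np
import pytest

import headfield as hf

# Small phantom used across the suite: head-like shell proportions at half
# scale so that solves take fractions of a second.
SMALL_RADII = (46.0, 43.0, 40.0, 38.0, 34.0)


@pytest.fixture(scope="session")
def small_head():
    return hf.make_sphere_head(SMALL_RADII, voxel_size=4.0)


@pytest.fixture(scope="session")
def small_electrodes(small_head):
    return hf.place_electrodes(small_head, 12, coverage_deg=160.0)


@pytest.fixture(scope="session")
def small_sources(small_head):
    return hf.extract_source_space(small_head, 60)


@pytest.fixture(scope="session")
def shell_sigma():
    return hf.TissueConductivityTable.three_shell()


@pytest.fixture(scope="session")
def small_leadfield(small_head, small_electrodes, small_sources, shell_sigma):
    return hf.compute_leadfield(small_head, shell_sigma, small_electrodes, small_sources)


def random_leadfield(seed, n_locations=20, n_electrodes=8):
    """Toy lead field with random matrices; no physics, for metric/scan tests."""
    rng = np.random.default_rng(seed)
    locations = rng.uniform(-40, 40, size=(n_locations, 3))
    normals = rng.normal(size=(n_locations, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    space = hf.CorticalSourceSpace(locations=locations, normals=normals)
    matrices = rng.normal(size=(n_locations, n_electrodes, 3))
    return hf.LeadField(
        matrices=matrices,
        electrode_names=[f"E{i:03d}" for i in range(n_electrodes)],
        source_space=space,
        reference_mode="common_average",
    )


@pytest.fixture
def toy_leadfield():
    return random_leadfield(seed=42)
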