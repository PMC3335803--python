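import numpy as np
import pytest

from ccfa import (
    PhantomConfig,
    build_atlas,
    extract_table,
    generate_density_maps,
    generate_fa_cohort,
)


@pytest.fixture(scope="session")
def phantom_cfg() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_atlas(phantom_cfg):
    """Atlas from 25 jittered phantom subjects at tau = 0.90."""
    maps = generate_density_maps(phantom_cfg, 25, seed=101)
    return build_atlas(maps, 0.90)


@pytest.fixture(scope="session")
def small_cohort(phantom_cfg):
    """A compact 3-group cohort: 8 subjects per group."""
    vols, manifest = generate_fa_cohort(
        phantom_cfg, {"AD": 8, "aMCI": 8, "HC": 8}, seed=202
    )
    volumes = {r.subject_id: v for r, v in zip(manifest, vols)}
    return vols, manifest, volumes


@pytest.fixture(scope="session")
def small_table(small_cohort, small_atlas):
    _, manifest, volumes = small_cohort
    return extract_table(manifest, small_atlas, 0.2, volumes=volumes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
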