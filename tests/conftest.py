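import numpy as np
import pytest

from marrowmap import GeneratorConfig, build_volume
from marrowmap.synthetic import SizeDistribution


def small_config(**overrides) -> GeneratorConfig:
    """A downsized scene for fast unit tests: same structure, less bulk."""
    cfg = GeneratorConfig()
    cfg.volume_extent_um = (1500.0, 1000.0, 35.0)
    cfg.pool_count = 3000
    cfg.vessel_params.n_sinusoids = 25
    cfg.vessel_params.n_arterioles = 5
    cfg.n_megakaryocytes = 15
    cfg.erythroid.n_sites = 5
    cfg.b_site.n_sites = 4
    cfg.myeloid.n_neutrophil_sites = 4
    cfg.myeloid.n_monodc_sites = 3
    cfg.hspc.counts = {"CD41- LT-HSC": 4, "ST-HSC": 6, "MkP": 6, "pre Meg-E": 6}
    cfg.pre_cfu_e.count = 20
    for key, value in overrides.items():
        obj = cfg
        *parents, leaf = key.split(".")
        for p in parents:
            obj = getattr(obj, p)
        setattr(obj, leaf, value)
    return cfg


@pytest.fixture(scope="session")
def default_scene():
    """One full default scene (the study conditions), seed 1."""
    return build_volume(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def small_scene():
    return build_volume(small_config(), seed=7)


def derive_scene_seeds(base_seed: int, n: int) -> list[int]:
    """Independent per-scene seeds derived from one base seed (< 2^31)."""
    return [
        int(c.generate_state(1)[0] % (2**31))
        for c in np.random.SeedSequence(base_seed).spawn(n)
    ]
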