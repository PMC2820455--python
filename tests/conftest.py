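import numpy as np
import pytest

from tauscreen.synth import Baselines, EffectSpec, NoiseModel

#: all noise sources off — exactness fixtures
QUIET = NoiseModel(cell_cv=0.0, well_cv=0.0, background_level=0.0, read_noise_sd=0.0)


@pytest.fixture
def quiet_noise() -> NoiseModel:
    return QUIET


@pytest.fixture
def baselines() -> Baselines:
    return Baselines()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201)


def make_effect(gene="G", phospho=1.0, total=1.0, cells=50.0) -> EffectSpec:
    return EffectSpec(gene, phospho_factor=phospho, total_factor=total, cell_count_mean=cells)
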