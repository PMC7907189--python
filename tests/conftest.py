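import numpy as np
import pytest

import lesionmap as lm
from lesionmap.core_volumes import LesionMask, VolumeGrid


def make_mask(data, subject_id="s", laterality="left", score=0, spacing=(1.0, 1.0, 1.0)):
    return LesionMask(
        grid=VolumeGrid(np.asarray(data, dtype=np.uint8), spacing=spacing),
        subject_id=subject_id,
        laterality=laterality,
        score=score,
    )


def random_mask(rng, shape, p=0.3, **kwargs):
    data = (rng.random(shape) < p).astype(np.uint8)
    if not data.any():
        data.flat[rng.integers(0, data.size)] = 1
    return make_mask(data, **kwargs)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic 35-subject cohort at the default study conditions."""
    return lm.simulate_cohort(lm.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_connectome():
    """One synthetic connectome dataset (35 seeds, 20 normative subjects)."""
    return lm.simulate_connectome(lm.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_rmaps(default_connectome):
    from lesionmap.normative_connectome import rmap

    conn = default_connectome
    return [rmap(s, conn.bold_series, grid=conn.layout.grid) for s in conn.patient_seeds]
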