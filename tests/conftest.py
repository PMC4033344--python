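import numpy as np
import pytest

import gaitdiff as gd

POP_SEED = 7
N_SUBJECTS = 10


@pytest.fixture(scope="session")
def population():
    """Default-condition walking population: 10 subjects x 2 sequences x 40 frames."""
    return gd.generate_population(N_SUBJECTS, 2, 40, seed=POP_SEED)


@pytest.fixture(scope="session")
def gallery_probes(population):
    gallery = [s for s in population if s.sequence_id == "seq00"]
    probes = [s for s in population if s.sequence_id == "seq01"]
    return gallery, probes


@pytest.fixture(scope="session")
def agdi_templates(population):
    return {(s.subject_id, s.sequence_id): gd.build_agdi(s) for s in population}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_template_stack(rng, M=10, m=8, n=6):
    """Random template images with cross-pixel correlation, values in [0, 1]."""
    base = rng.random((m, n))
    stack = np.clip(base + 0.3 * rng.standard_normal((M, m, n)), 0.0, 1.0)
    return stack
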