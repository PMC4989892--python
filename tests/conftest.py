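import numpy as np
import pytest

from pcafe.data_io import OmicsMatrix, SampleInfo
from pcafe.synthetic import SyntheticConfig, generate


def make_matrix(values, modality="expression", categories=None, replicates=None):
    """OmicsMatrix from a 2-D array with auto-generated metadata."""
    values = np.asarray(values, dtype=float)
    I, J = values.shape
    ids = [f"p{i:03d}" for i in range(I)]
    if categories is None:
        categories = [f"c{j}" for j in range(J)]
        replicates = [1] * J
    samples = [
        SampleInfo(f"s{j}", category=categories[j], replicate=replicates[j],
                   modality=modality)
        for j in range(J)
    ]
    return OmicsMatrix(values, ids, samples)


def design_matrix(rng, I, L=8, reps=3, effect_sd=0.0, modality="expression"):
    """I probes over an L x reps one-way design with optional category effects."""
    J = L * reps
    cats = np.repeat([f"cat{l}" for l in range(L)], reps)
    values = rng.standard_normal((I, J))
    if effect_sd:
        mu = rng.normal(0, effect_sd, size=(I, L))
        values += np.repeat(mu, reps, axis=1)
    ids = [f"p{i:04d}" for i in range(I)]
    samples = [
        SampleInfo(f"s{j}", category=cats[j], replicate=j % reps + 1,
                   modality=modality)
        for j in range(J)
    ]
    return OmicsMatrix(values, ids, samples)


@pytest.fixture(scope="session")
def small_paired():
    """A scaled-down planted dataset shared by fast tests."""
    cfg = SyntheticConfig(seed=11, n_probes=1000, n_planted=30)
    expr, meth, truth = generate(cfg)
    return cfg, expr, meth, truth
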