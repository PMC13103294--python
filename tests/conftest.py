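import numpy as np
import pytest

import foca
from foca.benchmarks import block_coupling
from foca.individualize import Parcellation
from foca.synthgen import EffectSpec, SubjectMeta


@pytest.fixture(scope="session")
def geometry():
    return foca.make_geometry(20, 20, spacing_mm=2.0)


@pytest.fixture(scope="session")
def clean_model(geometry):
    """K=5 block-structured model with no noise/global/boundary effects."""
    return foca.sample_latent_model(
        5, geometry, block_coupling(5),
        EffectSpec(noise_sd=0.0, global_weight=0.0, boundary_shift_rate=0.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def noisy_model(geometry):
    """K=5 model with realistic noise, global signal and boundary shifts."""
    return foca.sample_latent_model(
        5, geometry, block_coupling(5),
        EffectSpec(noise_sd=1.0, global_weight=0.5, boundary_shift_rate=0.1),
        seed=0,
    )


@pytest.fixture(scope="session")
def group_parcellation(clean_model):
    return Parcellation(labels=clean_model.group_labels, n_networks=5)


@pytest.fixture(scope="session")
def long_clean_scan(clean_model):
    return foca.simulate_scan(
        clean_model, SubjectMeta(subject_id="clean"), n_frames=5000, seed=1
    )


@pytest.fixture(scope="session")
def noisy_cohort(noisy_model):
    return foca.simulate_cohort(noisy_model, 12, n_frames=300, seed=2)


@pytest.fixture(scope="session")
def noisy_focas(noisy_cohort):
    out = []
    for s in noisy_cohort:
        parc = Parcellation(labels=s.true_labels, n_networks=5, level="individual")
        out.append(foca.compute_foca(foca.compute_topography(s, parc)))
    return out


def random_foca(rng, k=6, scale=0.2):
    v = np.clip(rng.normal(0, scale, size=(k, k)), -0.99, 0.99)
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 1.0)
    return foca.FocaMatrix(values=v)
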