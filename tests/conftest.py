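import numpy as np
import pytest

from twinpk import SimulationConfig


@pytest.fixture(scope="session")
def small_config():
    """A small cohort that still exercises every pipeline stage."""
    return SimulationConfig(n_mz_pairs=12, n_dz_pairs=6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_pairs(n_mz, n_dz, a2=0.0, d2=0.0, c2=0.0, e2=1.0, sigma=1.0, mean=0.0,
               seed=0, n_occasions=1, within_cv=0.0):
    """Direct (array-level) twin phenotype generator used as a light
    fixture for the model-fitting tests."""
    from twinpk.heritability import TwinPairSet
    from twinpk.simulate import simulate_twin_phenotypes

    cfg = SimulationConfig(
        n_mz_pairs=n_mz, n_dz_pairs=n_dz, a2=a2, d2=d2, c2=c2, e2=e2,
        log_cl_sd=sigma, seed=seed, n_occasions=n_occasions,
        within_subject_cv=within_cv,
    )
    subj, occ = simulate_twin_phenotypes(cfg)
    pairs = TwinPairSet.from_frame(subj, "log_cl")
    return pairs, subj, occ
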