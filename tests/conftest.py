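import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gcnkit as gk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_bundle():
    """6 genes x 8 samples (2 groups of 4), deterministic."""
    return gk.make_fixture("tiny")


@pytest.fixture(scope="session")
def hrr_demo():
    """6-gene x 8-sample FPKM matrix for exhaustive rank/HRR checks."""
    return gk.make_fixture("hrr_demo")


@pytest.fixture(scope="session")
def gba_demo():
    """8-node hand-built network with a planted 4-gene clique term."""
    return gk.make_fixture("gba_demo")


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate synthetic dataset shared by several module tests."""
    cfg = gk.SyntheticConfig(
        n_genes=300,
        n_groups=3,
        samples_per_group=8,
        n_modules=4,
        module_size=25,
        within_module_correlation=0.85,
        seed=13,
    )
    return gk.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_network(small_dataset):
    """Pooled HRR network at k=20 over the small synthetic dataset."""
    cm, _, _, _ = small_dataset
    fm = gk.filter_low_expression(gk.fpkm_normalize(cm))
    return gk.hrr_network_from_fpkm(fm, 20)
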