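import numpy as np
import pytest

from ntscreen.interface import load_config
from ntscreen.mixture_model import (
    DependentComponentParams,
    IndependentComponentParams,
    MixtureModelParams,
    ProportionCurve,
    TruncationLimits,
)


@pytest.fixture(scope="session")
def config():
    """The packaged synthetic-defaults configuration."""
    return load_config()


@pytest.fixture(scope="session")
def params(config):
    """Generative mixture truth (synthetic defaults)."""
    return config.params


@pytest.fixture(scope="session")
def anchors(config):
    return config.anchors


def make_params(**overrides):
    """Hand-assembled mixture parameters for degenerate-case tests.

    The independent components are well separated from zero (mu/sigma >= 6)
    so zero-truncation corrections are below 1e-9.
    """
    base = dict(
        unaffected_dep=DependentComponentParams(a=-0.3952520, b=0.0134496,
                                                c=-0.0000645919, sigma=0.085),
        unaffected_ind=IndependentComponentParams(mu=3.0, sigma=0.5),
        unaffected_prop=ProportionCurve(0.12, 0.03),
        affected_ind=IndependentComponentParams(mu=3.0, sigma=0.5),
        affected_prop_ind=0.94,
        truncation=TruncationLimits(0.3, 8.0, "mm"),
    )
    base.update(overrides)
    return MixtureModelParams(**base)


@pytest.fixture
def degenerate_lognormal_params():
    """Unaffected side collapses to the single lognormal component (pi = 0)."""
    return make_params(unaffected_prop=ProportionCurve(0.0, 0.0))


@pytest.fixture
def degenerate_gaussian_params():
    """Affected side collapses to the single (truncated) Gaussian component."""
    return make_params(affected_prop_ind=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
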