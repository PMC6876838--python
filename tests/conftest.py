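import numpy as np
import pytest

from minibeam import BeamSpec, GeneratorConfig, LQParams

#: sigma/ctc ratios of the six irradiated groups.
STUDY_RATIOS = (0.053, 0.110, 0.170, 0.228, 0.312, 0.491)


@pytest.fixture
def lq_keratinocyte() -> LQParams:
    return LQParams(alpha=0.2, beta=0.06)


@pytest.fixture
def spec_small() -> BeamSpec:
    """Smallest studied beam: sigma 95 μm on the 1.8 mm lattice."""
    return BeamSpec(sigma=95.0, ctc=1800.0, mean_dose=60.0)


@pytest.fixture
def spec_large() -> BeamSpec:
    """Near-homogeneous beam: sigma 883 μm on the 1.8 mm lattice."""
    return BeamSpec(sigma=883.0, ctc=1800.0, mean_dose=60.0)


@pytest.fixture
def default_generator() -> GeneratorConfig:
    return GeneratorConfig()


def brute_force_dose(x, y, sigma, ctc, mean_dose, k=60):
    """Independent truncated double-sum oracle for the lattice dose."""
    a = mean_dose * ctc**2 / (2.0 * np.pi * sigma**2)
    total = np.zeros_like(np.asarray(x, dtype=float))
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            total = total + np.exp(
                -((np.asarray(x) - i * ctc) ** 2 + (np.asarray(y) - j * ctc) ** 2)
                / (2.0 * sigma**2)
            )
    return a * total
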