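import numpy as np
import pytest

from phenosync.curves import CurveFamily, CurveSpec, SkewNormalParams, VExpParams
from phenosync.synthetic import default_paper_like_config


@pytest.fixture
def skewed_spec():
    """The reference asymmetric seasonal curve used across oracle tests."""
    return CurveSpec(
        CurveFamily.SKEW_NORMAL, SkewNormalParams(xi=140, omega=30, alpha=4)
    )


@pytest.fixture
def symmetric_spec():
    return CurveSpec(
        CurveFamily.SKEW_NORMAL, SkewNormalParams(xi=160, omega=25, alpha=0)
    )


@pytest.fixture
def dip_spec():
    """A soluble-sugar-style minimum curve."""
    return CurveSpec(
        CurveFamily.V_EXPONENTIAL, VExpParams(ymax=0.8, mu=1.002, xmax=200)
    )


def random_skew_specs(n, seed):
    """Randomized but reproducible skew-normal specs spanning realistic shapes."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        specs.append(
            CurveSpec(
                CurveFamily.SKEW_NORMAL,
                SkewNormalParams(
                    xi=float(rng.uniform(80, 260)),
                    omega=float(rng.uniform(10, 60)),
                    alpha=float(rng.uniform(-6, 6)),
                    amplitude=float(rng.uniform(0.2, 5.0)),
                ),
            )
        )
    return specs


@pytest.fixture
def tiny_config():
    """Down-scaled generator configuration for fast pipeline tests."""
    cfg = default_paper_like_config(seed=0)
    cfg.sites_per_biome = 4
    cfg.nsc_sites_per_biome = 3
    cfg.years = (2016,)
    return cfg
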