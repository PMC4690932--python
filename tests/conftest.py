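import numpy as np
import pytest

import sludgekit as sk


@pytest.fixture
def plant5_fit() -> sk.PowerLawFit:
    """Validation-plant thickening fit (a = 6.493, b = 0.0465)."""
    return sk.PowerLawFit(a=6.493, b=0.0465, r_squared=0.88, p_value=1e-4, n_points=30)


@pytest.fixture
def plant5_law() -> sk.CompressionLaw:
    return sk.CompressionLaw(a=6.493, b=0.0465, x0=1.0, X0=6.6)


@pytest.fixture
def vesilind() -> sk.VesilindFit:
    return sk.VesilindFit(v0=11.043, n=0.364)


@pytest.fixture
def integrated_model(vesilind, plant5_law) -> sk.IntegratedSettlingModel:
    """Integrated model with X_c at the branch crossover, where the
    compression branch is guaranteed to sit below the hindered one."""
    xc = sk.branch_crossover(vesilind, plant5_law)
    return sk.IntegratedSettlingModel(
        vesilind=vesilind, compression=plant5_law, X_c=xc
    )


@pytest.fixture
def exact_line_curve() -> sk.BatchSettlingCurve:
    t = np.arange(0.0, 21.0)
    return sk.BatchSettlingCurve(
        times=t, heights=1.0 - 0.02 * t, X0=3.0, x0=1.0
    )
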