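import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def panel29():
    """Default synthetic 29-compound panel plus its generating parameters."""
    from biomimqsar.synthetic import SimulationSpec, gen_panel

    return gen_panel(SimulationSpec(seed=1))


def exact_corr_columns(n: int, corr: np.ndarray, seed: int = 0) -> np.ndarray:
    """n x k matrix whose sample correlation matrix equals `corr` exactly.

    Centered random columns are orthonormalized (QR) and mixed with the
    Cholesky factor of the target matrix; linear combinations of centered
    columns stay centered, so the sample correlation is exact.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, k))
    Z = Z - Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    L = np.linalg.cholesky(corr)
    return Q @ L.T
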