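import numpy as np
import pytest

from fcros import ExpressionMatrix, SyntheticConfig, from_groups, generate_dataset
from fcros.datasets import worked_example


@pytest.fixture(scope="session")
def example_matrix() -> ExpressionMatrix:
    """MACF1/TREM2 10+10 worked-example matrix."""
    return worked_example()


@pytest.fixture
def random_matrix():
    """Factory for random two-condition matrices (no real DE structure)."""

    def make(n=50, m1=4, m2=3, seed=0) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        return from_groups(
            [f"g{i}" for i in range(n)],
            rng.normal(8.0, 1.0, size=(n, m1)),
            rng.normal(8.0, 1.0, size=(n, m2)),
        )

    return make


@pytest.fixture(scope="session")
def planted_dataset():
    """500-gene dataset with 10 up- and 10 down-regulated genes, low noise."""
    cfg = SyntheticConfig(
        n=500, m1=5, m2=5, p_de=0.04, sigma_n=0.1,
        lfc_min=2.0, lfc_max=3.0, up_fraction=0.5, seed=42,
    )
    ds = generate_dataset(cfg)
    assert ds.n_de == 20
    return ds
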