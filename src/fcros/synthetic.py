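"""Seeded simulator of two-condition expression data with known DE truth.

Emulates the usual microarray-simulation setup (in the spirit of MADSIM):
``n`` genes with uniform baseline log2 expression, a small fraction of
differentially expressed (DE) genes receiving a signed log2 shift in the
test group, and additive Gaussian noise of level ``sigma_n`` on every
observation.  Defaults reflect the standard study conditions: 10,000
genes, 7 + 7 samples, 2% DE (an expected 200 DE genes), noise level 0.2.

The generator is a stand-in, not a reimplementation of MADSIM: it
reproduces the headline parameters (n, proportion DE, group sizes,
sigma_n) and yields qualitatively similar M-A geometry, but not MADSIM's
intensity-dependent noise or its seed-exact outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "generate_two_batches"]


@dataclass
class SyntheticConfig:
    """Parameters of the simulator.

    Attributes
    ----------
    n : int
        Number of genes (default 10,000).
    m1, m2 : int
        Control / test sample counts (default 7 each).
    p_de : float
        Proportion of DE genes (default 0.02, i.e. 200 genes at n=10,000).
    sigma_n : float
        Additive Gaussian noise s.d. in log2 units (default 0.2).
    lfc_min, lfc_max : float
        Bounds of the planted absolute log2 fold change (default 0.6-3.0:
        from ~1.5-fold, near the edge of detectability, to 8-fold).
    baseline_low, baseline_high : float
        Uniform range of baseline log2 expression (default 4-14, a typical
        microarray dynamic range).
    up_fraction : float
        Share of DE genes shifted up (default 0.5, symmetric).
    seed : int
        Mandatory RNG seed; same seed, same matrix, bit for bit.
    """

    n: int = 10_000
    m1: int = 7
    m2: int = 7
    p_de: float = 0.02
    sigma_n: float = 0.2
    lfc_min: float = 0.6
    lfc_max: float = 3.0
    baseline_low: float = 4.0
    baseline_high: float = 14.0
    up_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.m1 < 1 or self.m2 < 1:
            raise ValueError("n >= 2 and m1, m2 >= 1 required")
        if not 0.0 <= self.p_de <= 1.0:
            raise ValueError("p_de must be in [0, 1]")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if self.lfc_min > self.lfc_max:
            raise ValueError("lfc_min must be <= lfc_max")
        if self.baseline_low >= self.baseline_high:
            raise ValueError("baseline_low must be < baseline_high")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """Simulated matrix plus its ground truth."""

    matrix: ExpressionMatrix
    de_indices: np.ndarray  # planted DE gene indices, sorted
    true_lfc: np.ndarray  # signed log2 effect per gene; 0 for non-DE
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def n_de(self) -> int:
        return self.de_indices.size

    def truth_set(self) -> set[int]:
        return set(int(i) for i in self.de_indices)


def _simulate(cfg: SyntheticConfig, rng: np.random.Generator,
              mu: np.ndarray, true_lfc: np.ndarray,
              de: np.ndarray) -> SyntheticDataset:
    """Draw one noisy realization around fixed gene means."""
    gene_means = np.tile(mu[:, None], (1, cfg.m1 + cfg.m2))
    gene_means[:, cfg.m1:] += true_lfc[:, None]
    values = gene_means + rng.normal(0.0, cfg.sigma_n, size=gene_means.shape)
    matrix = ExpressionMatrix(
        gene_ids=[f"g{i:05d}" for i in range(cfg.n)],
        values=values,
        control_indices=list(range(cfg.m1)),
        test_indices=list(range(cfg.m1, cfg.m1 + cfg.m2)),
    )
    return SyntheticDataset(matrix=matrix, de_indices=de,
                            true_lfc=true_lfc, config=cfg)


def _plant_truth(cfg: SyntheticConfig, rng: np.random.Generator):
    n_de = int(round(cfg.n * cfg.p_de))
    if n_de == 0 and cfg.p_de > 0:
        warnings.warn(f"p_de={cfg.p_de} rounds to zero DE genes at n={cfg.n}")
    de = np.sort(rng.choice(cfg.n, size=n_de, replace=False))
    mu = rng.uniform(cfg.baseline_low, cfg.baseline_high, size=cfg.n)
    true_lfc = np.zeros(cfg.n)
    if n_de:
        mag = rng.uniform(cfg.lfc_min, cfg.lfc_max, size=n_de)
        sign = np.where(rng.random(n_de) < cfg.up_fraction, 1.0, -1.0)
        true_lfc[de] = sign * mag
    return mu, true_lfc, de


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Simulate one two-condition dataset with planted DE genes.

    Baselines are uniform on [baseline_low, baseline_high]; each of the
    ``round(n * p_de)`` DE genes gets a signed shift of magnitude uniform
    on [lfc_min, lfc_max] added to its test samples; iid Gaussian noise of
    s.d. ``sigma_n`` is added to every observation.  Fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    mu, true_lfc, de = _plant_truth(cfg, rng)
    return _simulate(cfg, rng, mu, true_lfc, de)


def generate_two_batches(
    cfg: SyntheticConfig, batch_shift: float = 0.0, seed2: int | None = None
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Two batches sharing gene set and DE truth, differing in noise.

    Both batches are built around the same gene baselines and planted
    effects; the second batch adds a constant ``batch_shift`` to every
    value (a global batch bias that within-batch ranking must ignore) and,
    unless ``seed2 == cfg.seed``, draws independent noise from ``seed2``.
    ``seed2 = cfg.seed`` with ``batch_shift = 0`` duplicates batch 1
    exactly.
    """
    rng1 = np.random.default_rng(cfg.seed)
    mu, true_lfc, de = _plant_truth(cfg, rng1)
    b1 = _simulate(cfg, rng1, mu, true_lfc, de)

    if seed2 is None:
        seed2 = cfg.seed + 1
    if seed2 == cfg.seed:
        # replay the same stream: identical noise, hence a true duplicate
        rng2 = np.random.default_rng(cfg.seed)
        _plant_truth(cfg, rng2)  # advance past the truth draws
    else:
        rng2 = np.random.default_rng(seed2)
    b2 = _simulate(cfg, rng2, mu, true_lfc, de)
    b2.matrix.values += batch_shift
    return b1, b2
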