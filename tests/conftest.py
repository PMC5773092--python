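import numpy as np
import pandas as pd
import pytest

from histosig import ExpressionMatrix, GeneSignature, TwoClassContrast
from histosig.simulate import (
    BatchSpec,
    CohortConfig,
    HistologySpec,
    MixtureSpec,
    default_config,
    simulate_cohort,
)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, simple values for hand checks."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0],
            "s2": [2.0, 2.0, 5.0],
            "s3": [4.0, 2.0, 5.0],
            "s4": [10.0, 2.0, 5.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def contrast_2v2_matrix():
    """One informative gene for the hand-computed d example (2v2)."""
    values = pd.DataFrame(
        {
            "a1": [2.0, 5.0],
            "a2": [4.0, 5.0],
            "b1": [0.0, 5.0],
            "b2": [2.0, 5.0],
        },
        index=["g_diff", "g_const"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def contrast_2v2():
    return TwoClassContrast("t_vs_r", ["a1", "a2"], ["b1", "b2"])


@pytest.fixture
def toy_3v3():
    """6-gene 3v3 matrix with fixed values for exhaustive permutation checks."""
    rng = np.random.default_rng(42)
    base = rng.normal(8, 1, size=(6, 6))
    base[0, :3] += 3.0  # one strongly up gene
    base[1, :3] -= 2.5  # one down gene
    values = pd.DataFrame(
        base,
        index=[f"g{i}" for i in range(6)],
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )
    m = ExpressionMatrix(values)
    c = TwoClassContrast("t_vs_r", ["a1", "a2", "a3"], ["b1", "b2", "b3"])
    return m, c


def compact_cohort(seed, effect=2.0, n_per_class=10, noise_sd=1.0, n_classes=4,
                   n_genes=2000, mixtures=(), with_batch=True):
    """Smaller cohort for multi-seed simulations."""
    names = ["squamous", "emt", "microacinar", "papillary", "solid",
             "adenomyoepithelial"][:n_classes]
    cfg = CohortConfig(
        n_genes=n_genes,
        histologies=[
            HistologySpec(n, n_samples=n_per_class, n_up_planted=40,
                          n_down_planted=20, effect_log2=effect)
            for n in names
        ],
        genotype_batches=[BatchSpec("genotypeA")] if with_batch else [],
        noise_sd=noise_sd,
        mixtures=list(mixtures),
        seed=seed,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(default_config(seed=11))


@pytest.fixture
def planted_signature(default_cohort):
    m, truth = default_cohort
    return GeneSignature(
        "SQUAMOUS", truth.planted_up["squamous"], truth.planted_down["squamous"]
    )
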