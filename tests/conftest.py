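import numpy as np
import pandas as pd
import pytest

from coexkit.synthetic import CohortConfig, generate_cohort
from coexkit.types import ExpressionMatrix, SampleTraits


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort shared across tests (2 modules, fast)."""
    cfg = CohortConfig(
        n_genes=400,
        n_samples=120,
        n_modules=2,
        module_sizes=(60, 40),
        noise_sd=0.4,
        zero_inflation=0.3,
        relapse_effect=1.5,
        survival_effect=1.0,
        seed=42,
    )
    expr, traits, truths = generate_cohort(cfg)
    return cfg, expr, traits, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_expression(values, scale="log2", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    genes = genes or [f"g{i}" for i in range(g)]
    samples = samples or [f"s{j}" for j in range(s)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            scale=scale)


def make_traits(samples, **columns):
    return SampleTraits(pd.DataFrame(columns, index=list(samples)))
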