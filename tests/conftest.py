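import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bloodsig import ExpressionMatrix, PhenotypeTable
from bloodsig.simulate import ModuleSpec, SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150821)


@pytest.fixture
def small_expr(rng):
    """10 genes x 12 samples of Gaussian log2-like values."""
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{i}" for i in range(12)]
    values = pd.DataFrame(rng.normal(7, 1, (10, 12)), index=genes,
                          columns=samples)
    return ExpressionMatrix(values, platform="microarray_log2")


@pytest.fixture
def labelled_pheno(small_expr):
    samples = small_expr.sample_ids
    half = len(samples) // 2
    return PhenotypeTable(pd.DataFrame(
        {"risk_label": ["high"] * half + ["low"] * (len(samples) - half)},
        index=pd.Index(samples, name="sample_id")))


def two_block_config(seed=0, n_ref=200, background=100):
    """Two planted co-expression blocks plus independent background genes."""
    return SimulationConfig(
        n_genes=2 * 30 + background,
        module_specs=[
            ModuleSpec("block_a", 30, "up", 0.7, 1.0, True),
            ModuleSpec("block_b", 30, "up", 0.7, 1.0, True),
        ],
        n_reference_1=n_ref, n_reference_2=n_ref, seed=seed)
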