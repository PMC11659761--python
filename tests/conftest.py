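import numpy as np
import pandas as pd
import pytest

from agingscreen import ExpressionMatrix, SimulationConfig, simulate_aging_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expr():
    """3 genes x 4 samples log2 matrix."""
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 2.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(vals, scale="log2")


@pytest.fixture(scope="session")
def planted_cohort():
    """One-tissue aging cohort with strong planted trends (shared across
    tests; treat as read-only)."""
    cfg = SimulationConfig(
        n_genes=2000, n_samples_per_tissue=150,
        tissues={"hippocampus": "i"},
        frac_down=0.10, frac_up=0.05,
        slope_down=-0.052, slope_up=0.052,
        noise_sd=1.0, seed=11,
    )
    matrices, samples, truth = simulate_aging_cohort(cfg)
    return matrices["hippocampus"], samples, truth


def make_call_table(genes, r, p, call, tissue="t"):
    table = pd.DataFrame(
        {"r": r, "p": p, "n": 50, "call": call},
        index=pd.Index(genes, name="gene"),
    )
    table.attrs["tissue"] = tissue
    return table
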