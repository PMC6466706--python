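import numpy as np
import pandas as pd
import pytest

from senesig import ExpressionMatrix, SimulationConfig, generate_paired_dataset


@pytest.fixture
def small_matrix():
    """6 probes x 4 samples with known values and all-detected p-values."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8, 1, (6, 4)),
        index=[f"p{i}" for i in range(6)],
        columns=["s1", "s2", "s3", "s4"],
    )
    detp = pd.DataFrame(0.01, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, detp)


@pytest.fixture(scope="session")
def small_study():
    """A small planted two-condition study shared across tests."""
    cfg = SimulationConfig(
        n_genes=600, probes_per_gene=(1, 3), n_samples_per_arm=4,
        n_shared_up=40, n_shared_down=40, n_specific_A=30, n_specific_B=30,
        effect_log2fc=2.0, noise_sd=0.5, detection_fail_rate=0.1, seed=11,
    )
    mat_A, mat_B, annotation, truth = generate_paired_dataset(cfg)
    return {"config": cfg, "A": mat_A, "B": mat_B,
            "annotation": annotation, "truth": truth}


def make_matrix(X, detp=None, prefix="p"):
    X = np.asarray(X, dtype=float)
    idx = [f"{prefix}{i}" for i in range(X.shape[0])]
    cols = [f"s{j}" for j in range(X.shape[1])]
    dp = None
    if detp is not None:
        dp = pd.DataFrame(np.asarray(detp, dtype=float), index=idx, columns=cols)
    return ExpressionMatrix(pd.DataFrame(X, index=idx, columns=cols), dp)
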