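import numpy as np
import pandas as pd
import pytest

from bbscreen import a4_like_spec, generate_cohort, group2_like_spec


@pytest.fixture(scope="session")
def a4_cohort_50k():
    """Large calibrated cohort shared by the stochastic closure checks."""
    return generate_cohort(a4_like_spec(50_000, seed=12345))


@pytest.fixture(scope="session")
def group2_cohort_50k():
    return generate_cohort(group2_like_spec(50_000, seed=20221))


@pytest.fixture()
def tiny_cohort_frame():
    """Hand-written 20-row table with known amyloid status for oracle checks."""
    rng = np.random.default_rng(7)
    n = 20
    amyloid = np.array([1] * 6 + [0] * 14)
    apoe = np.array([0.9, 0.8, 0.5, 0.4, 0.3, 0.6,
                     0.7, 0.75, 0.2, 0.3, 0.5, 0.55, 0.6, 0.35,
                     0.45, 0.25, 0.65, 0.5, 0.4, 0.3])
    ptau = np.array([1.5, 0.9, 1.2, 0.85, 0.7, 0.95,
                     0.6, 1.1, 0.5, 0.82, 0.84, 0.7, 0.9, 0.75,
                     0.65, 0.55, 0.8, 0.78, 0.88, 0.6])
    return pd.DataFrame(
        {
            "id": [f"T{i:02d}" for i in range(n)],
            "amyloid_true": amyloid,
            "apoe4p_carrier_true": (apoe > 0.668).astype(int),
            "apoe4p_conc": apoe,
            "ptau181": ptau,
            "gfap": rng.uniform(50, 200, n),
            "abeta42": rng.uniform(30, 60, n),
            "abeta40": rng.uniform(200, 400, n),
            "pet_result": np.where(amyloid == 1, "positive", "negative"),
            "csf_ptau181": np.full(n, np.nan),
            "csf_abeta42": np.full(n, np.nan),
        }
    )
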