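import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def block_fixture():
    """Standard planted-structure fixture: 5 blocks x 10 features,
    within-block correlation 0.85, zero cross-block correlation, n=100."""
    from holofast.synthetic import make_planted_blocks

    data, labels, latents = make_planted_blocks(
        n_samples=100, n_blocks=5, block_size=10, within_corr=0.85, rng=42
    )
    return data, labels, latents


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (10 fed + 9 deprived)."""
    from holofast.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def naive_bh(p):
    """Independent step-up BH transcription used as the FDR oracle."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def reference_bicor(x, y):
    """Direct transcription of the biweight midcorrelation definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - v.mean()
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        return (v - med) * w

    a = weights(x)
    b = weights(y)
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


def reference_tom_dissimilarity(A):
    """Triple-loop transcription of unsigned topological overlap."""
    A = np.asarray(A, float)
    n = A.shape[0]
    k = np.array([sum(A[i, j] for j in range(n) if j != i) for i in range(n)])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            tom = (shared + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
            D[i, j] = 1.0 - tom
    return D


def random_corr_table(rng, n_rows=60):
    """Random long-form correlation table with mixed entity types."""
    types = ["host", "metabolite", "otu", "lipid"]
    rows = []
    for i in range(n_rows):
        ta, tb = rng.choice(types), rng.choice(types)
        rows.append(
            (
                f"{ta}_{i}a",
                ta,
                f"{tb}_{i}b",
                tb,
                float(rng.uniform(-1, 1)),
                float(rng.uniform(0, 1)),
            )
        )
    table = pd.DataFrame(
        rows, columns=["entity_a", "type_a", "entity_b", "type_b", "rho", "p"]
    )
    table["fdr"] = rng.uniform(0, 1, n_rows)
    table["star"] = ""
    return table
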