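import numpy as np
import pandas as pd
import pytest

from targetmr import LDPanel, simulate_scenario


def make_harmonized(rng, n, beta=0.5, se_y_scale=0.05, intercept=0.0):
    """Random harmonized table with outcome betas proportional to exposure betas."""
    bx = rng.uniform(0.02, 0.2, n)
    se_x = rng.uniform(0.002, 0.01, n)
    se_y = rng.uniform(0.5, 1.5, n) * se_y_scale
    by = intercept + beta * bx + rng.normal(0, se_y)
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(n)],
        "EA": "A", "OA": "G",
        "BETA_X": bx, "SE_X": se_x, "BETA_Y": by, "SE_Y": se_y,
        "EAF_X": 0.2, "EAF_Y": 0.2, "palindromic": False, "proxy_of": None,
    })


def small_panel(r: np.ndarray, mafs=None, palindromic=()):
    """Panel with n variants on one chromosome, 50 kb apart."""
    n = r.shape[0]
    mafs = mafs if mafs is not None else [0.2] * n
    rows = []
    for i in range(n):
        ea, oa = ("A", "T") if i in palindromic else ("A", "G")
        rows.append({"SNP": f"rs{i + 1}", "CHR": "1", "POS": 1_000_000 + 50_000 * i,
                     "A1": ea, "A2": oa, "MAF": mafs[i]})
    return LDPanel(variants=pd.DataFrame(rows), r=np.asarray(r, dtype=float))


@pytest.fixture(scope="session")
def causal_study():
    return simulate_scenario("causal", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
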