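import numpy as np
import pandas as pd
import pytest

from gxegblup import (Coding, MarkerMatrix, MultiEnvGBLUP,
                      PhenotypeTable, compute_K)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_marker_matrix(rng, n_lines=8, n_markers=60,
                         coding=Coding.BIALLELIC_012, missing_rate=0.0):
    hi = 3 if coding is Coding.BIALLELIC_012 else 2
    d = rng.integers(0, hi, size=(n_lines, n_markers)).astype(float)
    if missing_rate > 0:
        d[rng.uniform(size=d.shape) < missing_rate] = np.nan
    return MarkerMatrix([f"l{i}" for i in range(n_lines)],
                        [f"m{j}" for j in range(n_markers)], d, coding)


def make_small_dataset(rng, n=8, t=2, reps=2, n_markers=60, h2=0.5,
                       rho=0.6):
    """Tiny genotype + phenotype pair for solver tests, with a K and
    phenotypes generated under the model itself."""
    mm = random_marker_matrix(rng, n, n_markers)
    K = compute_K(mm)
    envs = [f"E{j + 1}" for j in range(t)]
    G = np.full((t, t), rho)
    np.fill_diagonal(G, 1.0)
    # genetic values with covariance G x K (up to PSD bending of K)
    evals, evecs = np.linalg.eigh(K.K)
    Khalf = (evecs * np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    u = Khalf @ rng.standard_normal((n, t)) @ np.linalg.cholesky(G).T
    s2 = (1.0 - h2) / h2
    rows = []
    for j, e in enumerate(envs):
        for r in range(reps):
            vals = j + u[:, j] + rng.normal(0, np.sqrt(s2), size=n)
            for i, l in enumerate(mm.line_ids):
                rows.append((l, e, f"r{r + 1}", vals[i]))
    pheno = PhenotypeTable(pd.DataFrame(
        rows, columns=["line", "env", "rep", "value"]))
    return pheno, K


@pytest.fixture
def small_dataset(rng):
    return make_small_dataset(rng)


@pytest.fixture
def small_model(small_dataset):
    pheno, K = small_dataset
    return MultiEnvGBLUP(pheno, K)
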