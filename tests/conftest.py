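"""Shared fixtures: small random submodels and TSV writers."""

import numpy as np
import pandas as pd
import pytest

from xshadow.model import GeneSubmodel, ModelParameters


def random_submodel(rng, max_m=3, max_n=3, allow_missing=True):
    """A small random gene submodel with arbitrary emission evidence."""
    M = int(rng.integers(1, max_m + 1))
    N = int(rng.integers(1, max_n + 1))
    y = rng.normal(size=(M, N))
    if allow_missing and rng.random() < 0.3:
        y[rng.integers(0, M), rng.integers(0, N)] = np.nan
    log_em = rng.normal(scale=1.5, size=(M, N, 3))
    log_em[~np.isfinite(y)] = np.nan
    off = rng.dirichlet(np.ones(3), size=(M, N))
    return GeneSubmodel(
        gene="g",
        patients=[f"p{i}" for i in range(M)],
        neighbours=[f"n{j}" for j in range(N)],
        weights=rng.uniform(0.2, 1.0, size=N),
        y=y,
        log_emission=log_em,
        offline_posterior=off,
        h=rng.integers(0, 2, size=N),
    )


def random_params(rng):
    f0, f1 = sorted(rng.uniform(0.05, 0.95, size=2))
    g0 = rng.dirichlet([2.0, 10.0, 2.0])
    up = rng.dirichlet([1.0, 4.0, 6.0])
    down = up[::-1].copy()
    # respect the identifiability constraints of the parameter container
    up[2] = max(up[2], g0[2] + 0.01)
    up /= up.sum()
    down[0] = max(down[0], g0[0] + 0.01)
    down /= down.sum()
    return ModelParameters(
        theta_d=float(rng.uniform(0.2, 0.8)),
        theta_f_d0=float(f0),
        theta_f_d1=float(f1),
        theta_g_f0=g0,
        theta_g_f1_up=up,
        theta_g_f1_down=down,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, frame: pd.DataFrame, index=False):
        p = tmp_path / name
        frame.to_csv(p, sep="\t", index=index)
        return p

    return _write
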