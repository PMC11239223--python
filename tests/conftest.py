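import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from phosreport.io import Proteome


@pytest.fixture
def toy_proteome() -> Proteome:
    """Small hand-built proteome exercising all five site-key scenarios.

    P1: single occurrence peptides ("AASK" at 3, "TTYSAK" at 8)
    P2: "ASSK" occurs twice (starts 2 and 8) -> repeated-peptide scenario
    P3/P4: both contain "LSDEK" (starts 2 and 4) -> multi-isoform scenario
    P5: "SSTSYR" at 3 hosts >=3 phospho groups
    """
    entries = {
        "P1": "MKAASKRTTYSAK",
        "P2": "MASSKGGASSKR",
        "P3": "MLSDEKR",
        "P4": "GGGLSDEKR",
        "P5": "MKSSTSYRA",
    }
    return Proteome(entries=entries, descriptions={a: a for a in entries})


def maxlfq_oracle(values: np.ndarray, min_shared_ions: int = 1) -> np.ndarray:
    """Brute-force MaxLFQ reference: explicit pairwise median log-ratios,
    Laplacian pseudoinverse per scipy-found connected component, then a
    shift to the mean-observed-log2 anchor.  Deliberately a different
    code path from the package implementation."""
    with np.errstate(divide="ignore", invalid="ignore"):
        X = np.log2(np.asarray(values, dtype=float))
    n = X.shape[1]
    obs = np.isfinite(X)
    active = obs.any(axis=0)
    adjacency = np.zeros((n, n))
    R = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = obs[:, i] & obs[:, j]
            if shared.sum() >= max(min_shared_ions, 1):
                adjacency[i, j] = 1.0
                R[i, j] = np.median(X[shared, j] - X[shared, i])
    out = np.full(n, np.nan)
    n_comp, labels = connected_components(adjacency, directed=False)
    for c in range(n_comp):
        members = [s for s in range(n) if labels[s] == c and active[s]]
        if not members:
            continue
        anchor = sum(X[obs[:, s], s].mean() for s in members)
        k = len(members)
        if k == 1:
            out[members[0]] = anchor
            continue
        # normal equations of sum over ordered shared pairs of
        # (w_j - w_i - r_ij)^2, solved by pseudoinverse
        L = np.zeros((k, k))
        rhs = np.zeros(k)
        for a, i in enumerate(members):
            for b, j in enumerate(members):
                if a == b or not adjacency[i, j]:
                    continue
                L[a, a] += 1.0
                L[a, b] -= 1.0
                rhs[a] -= R[i, j] - R[j, i]
        w = np.linalg.pinv(L) @ (rhs / 2.0)
        w = w + (anchor - w.sum()) / k
        for a, s in enumerate(members):
            out[s] = w[a]
    return out


def random_ion_matrix(rng: np.random.Generator, max_ions: int = 8,
                      max_samples: int = 6, max_missing: float = 0.5) -> np.ndarray:
    """Random raw-intensity matrix with NaN missingness for oracle tests."""
    n_ions = int(rng.integers(1, max_ions + 1))
    n_samples = int(rng.integers(2, max_samples + 1))
    log2_values = rng.normal(15.0, 2.0, size=(n_ions, n_samples))
    values = np.power(2.0, log2_values)
    mask = rng.random((n_ions, n_samples)) < rng.uniform(0.0, max_missing)
    values[mask] = np.nan
    return values
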