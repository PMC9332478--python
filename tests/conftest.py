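import numpy as np
import pandas as pd
import pytest

from aromadrivers import paper_fixtures, compute_oav


def eigen_pls1(X, y, n_components):
    """Independent PLS1 oracle: per component the weight vector is the
    dominant eigenvector of X' y y' X (via eigendecomposition rather than the
    NIPALS normalization), followed by the same deflation algebra."""
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).copy()
    Xc = X - X.mean(0)
    Xc = Xc / Xc.std(0, ddof=1)
    yc = y - y.mean()
    W, P, q = [], [], []
    for _ in range(n_components):
        cov = Xc.T @ yc
        M = np.outer(cov, cov)
        _, vecs = np.linalg.eigh(M)
        w = vecs[:, -1]
        if w @ cov < 0:  # eigenvector sign is arbitrary
            w = -w
        t = Xc @ w
        tt = t @ t
        p = Xc.T @ t / tt
        qa = yc @ t / tt
        Xc = Xc - np.outer(t, p)
        yc = yc - qa * t
        W.append(w)
        P.append(p)
        q.append(qa)
    W, P, q = np.column_stack(W), np.column_stack(P), np.asarray(q)
    return W @ np.linalg.solve(P.T @ W, q)


@pytest.fixture(scope="session")
def pls_oracle():
    return eigen_pls1


@pytest.fixture(scope="session")
def bundle():
    """Packaged reference tables (catalog, curves, concentrations, OAVs)."""
    return paper_fixtures()


@pytest.fixture(scope="session")
def oav_implied(bundle):
    """OAV matrix computed with the literature-implied thresholds for the two
    compounds whose printed thresholds are inconsistent with the OAV table."""
    return compute_oav(bundle.concentrations, bundle.catalog_implied)


@pytest.fixture()
def toy_liking():
    """Nine consumers in three well-separated liking archetypes."""
    rows = (
        [[1, 1, 7, 7, 1, 1]] * 3
        + [[7, 7, 1, 1, 1, 1]] * 3
        + [[1, 1, 1, 1, 7, 7]] * 3
    )
    return pd.DataFrame(
        rows,
        index=[f"C{i}" for i in range(9)],
        columns=[f"B{j + 1}" for j in range(6)],
        dtype=float,
    )
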