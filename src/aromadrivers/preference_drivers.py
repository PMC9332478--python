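"""Preference-driver ranking: per-cluster PLS regression of liking on the
volatile matrix, with absolute-coefficient relative importance.

External preference mapping with very few products and many collinear
predictors is the textbook use case for partial least squares.  The PLS1
model is fit by NIPALS: per component, a weight vector (the dominant
covariance direction between X and y), X scores, X/y loadings, then deflation
of X; regression coefficients are assembled as ``B = W (P'W)^{-1} q``.  The
relative importance of predictor j is ``100 * |b_j| / sum_k |b_k|``, and the
per-cluster driver report ranks predictors by that percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantification import ConcentrationMatrix

__all__ = [
    "PLSModel",
    "plsr_fit",
    "pls_predict",
    "relative_importance",
    "DriverReport",
    "fit_cluster_drivers",
]


@dataclass
class PLSModel:
    """Fitted PLS1 model on the centered/standardized problem.

    ``coef`` holds one regression coefficient per predictor on the
    standardized scale (zero for predictors dropped as zero-variance).
    """

    n_components: int
    predictors: list
    x_weights: np.ndarray        # predictors x components (W)
    x_loadings: np.ndarray       # predictors x components (P)
    y_loadings: np.ndarray       # components (q)
    x_scores: np.ndarray         # samples x components (T)
    coef: np.ndarray             # predictors
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    x_variance_explained: np.ndarray
    y_variance_explained: np.ndarray
    dropped: list


def plsr_fit(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    n_components: int = 2,
    scale: bool = True,
    tol: float = 1e-12,
) -> PLSModel:
    """Fit PLS1 (single response) by NIPALS.

    X columns are centered and, when ``scale``, divided by their sample
    standard deviation; y is centered.  Zero-variance predictors are dropped
    with a warning-equivalent (their coefficient and importance are 0).  A
    constant y is an error: there is no signal to regress.
    """
    Xdf = pd.DataFrame(X).copy()
    yv = np.asarray(y, dtype=float).ravel()
    n, m = Xdf.shape
    if yv.shape[0] != n:
        raise ValueError("X and y disagree on sample count")
    if n_components > min(n - 1, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, predictors)"
            f"={min(n - 1, m)}"
        )
    if np.isnan(Xdf.to_numpy()).any() or np.isnan(yv).any():
        raise ValueError("missing cells in PLS input")

    x_mean = Xdf.to_numpy().mean(axis=0)
    x_std = Xdf.to_numpy().std(axis=0, ddof=1)
    dropped = [c for c, s in zip(Xdf.columns, x_std) if s == 0]
    keep = np.asarray([s != 0 for s in x_std])
    y_mean = float(yv.mean())
    yc = yv - y_mean
    if np.allclose(yc, 0):
        raise ValueError("no signal: y is constant")

    Xc = (Xdf.to_numpy() - x_mean)[:, keep]
    if scale:
        Xc = Xc / x_std[keep]
    ss_x_total = float((Xc**2).sum())
    ss_y_total = float((yc**2).sum())

    m_kept = Xc.shape[1]
    W = np.zeros((m_kept, n_components))
    P = np.zeros((m_kept, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ss_x = np.zeros(n_components)
    ss_y = np.zeros(n_components)

    Xd, yd = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm <= tol:
            # residual covariance exhausted; later components stay zero
            W, P, T = W[:, : a], P[:, : a], T[:, : a]
            q, ss_x, ss_y = q[:a], ss_x[:a], ss_y[:a]
            n_components = a
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, qa
        ss_x[a] = tt * float(p @ p) / ss_x_total
        ss_y[a] = qa**2 * tt / ss_y_total

    if n_components == 0:
        raise ValueError("no signal: X carries no covariance with y")

    beta_kept = W @ np.linalg.solve(P.T @ W, q)
    coef = np.zeros(m)
    coef[keep] = beta_kept

    # expand weight/loading matrices back to the full predictor set
    def expand(mat: np.ndarray) -> np.ndarray:
        full = np.zeros((m, mat.shape[1]))
        full[keep] = mat
        return full

    return PLSModel(
        n_components=n_components,
        predictors=list(Xdf.columns),
        x_weights=expand(W),
        x_loadings=expand(P),
        y_loadings=q,
        x_scores=T,
        coef=coef,
        x_mean=x_mean,
        x_std=np.where(keep, x_std, 1.0) if scale else np.ones(m),
        y_mean=y_mean,
        x_variance_explained=ss_x,
        y_variance_explained=ss_y,
        dropped=dropped,
    )


def pls_predict(model: PLSModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predict y from raw-scale X using the fitted standardized model."""
    x = np.asarray(pd.DataFrame(X), dtype=float)
    xs = (x - model.x_mean) / model.x_std
    return xs @ model.coef + model.y_mean


def relative_importance(model: PLSModel) -> np.ndarray:
    """Percentage importance 100*|b_j| / sum|b|; sums to 100 exactly."""
    absb = np.abs(model.coef)
    total = absb.sum()
    if total == 0:
        raise ValueError("no signal: all PLS coefficients are zero")
    return 100.0 * absb / total


@dataclass
class DriverReport:
    cluster: int
    table: pd.DataFrame          # per-compound coefficient + importance
    top: pd.DataFrame            # top-k rows of table by importance

    def top_compounds(self) -> list:
        return list(self.top.index)


def fit_cluster_drivers(
    conc: ConcentrationMatrix,
    cluster_liking_means: pd.DataFrame,
    n_components: int = 2,
    top_k: int = 5,
    scale: bool = True,
    X: pd.DataFrame | None = None,
) -> list[DriverReport]:
    """Rank volatile drivers of liking for each consumer cluster.

    ``X`` defaults to the product x compound concentration means with
    TRACE/censored cells as 0 (below-threshold presence carries negligible
    signal); ``cluster_liking_means`` is the cluster x product table of mean
    liking.  One PLS1 fit per cluster; compounds are ranked by relative
    importance, ties broken by compound_id.
    """
    if X is None:
        X = conc.numeric().fillna(0.0)
    products = list(X.index)
    if len(products) < 3:
        raise ValueError("need at least 3 products for a driver fit")
    missing = [p for p in products if p not in cluster_liking_means.columns]
    if missing:
        raise ValueError(f"liking means missing products: {missing}")

    reports = []
    for cluster in cluster_liking_means.index:
        y = cluster_liking_means.loc[cluster, products].astype(float)
        model = plsr_fit(X, y, n_components=n_components, scale=scale)
        imp = relative_importance(model)
        table = pd.DataFrame(
            {"coefficient": model.coef, "relative_importance": imp},
            index=pd.Index(X.columns, name="compound_id"),
        )
        ranked = table.sort_values(
            ["relative_importance", "compound_id"],
            ascending=[False, True],
            kind="stable",
        )
        reports.append(
            DriverReport(cluster=cluster, table=table, top=ranked.head(top_k))
        )
    return reports
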