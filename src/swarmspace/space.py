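"""The swarm space: PCA and t-SNE embeddings of event metric vectors.

Each event of collective motion is a point in metric space (nine retained
metrics; the mean absolute bearing duplicates frontness and is excluded by
default). Standardizing the metrics and eigendecomposing their correlation
matrix gives the principal axes of variation across events — the linear
"swarm space" in which events from different species and datasets can be
compared. Eigenvalues are on the variance-of-a-standardized-metric scale, so
axes with eigenvalue below 1 carry less information than a single metric.
A t-SNE embedding complements the PCA by preserving local neighbourhoods.

Both embeddings are scikit-learn-style estimators (``fit`` /``transform``,
fitted attributes with trailing underscores) and compose with sklearn
pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.manifold import TSNE

from .metrics import DEFAULT_SWARM_METRICS


class ZeroVarianceError(ValueError):
    """A metric column has no variance and cannot be standardized."""


def _as_frame(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    if df.isna().any().any():
        raise ValueError("metric table contains missing values")
    return df.astype(float)


def standardize(table) -> pd.DataFrame:
    """z-score each column (mean 0, sample SD 1)."""
    df = _as_frame(table)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = df.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ZeroVarianceError(f"zero-variance column(s): {dead}")
    return (df - df.mean()) / sd


class SwarmSpacePCA(BaseEstimator, TransformerMixin):
    """PCA of standardized event metrics via the correlation matrix.

    Parameters
    ----------
    standardize : z-score the input columns before decomposition (default).
        With ``False`` the covariance matrix is decomposed instead, losing
        the eigenvalue-versus-1 interpretation.

    Fitted attributes
    -----------------
    eigenvalues_ : (p,) descending; sums to p for standardized input.
    variance_explained_pct_ : (p,) percentages, summing to 100.
    loadings_ : DataFrame (metric x axis) of unit eigenvectors, signs fixed
        so each axis's largest-|loading| metric loads positive.
    contributions_pct_ : DataFrame (metric x axis); 100 x squared loading,
        summing to 100 per axis (the factor-map convention).
    scores_ : DataFrame (row x axis); variance on axis k equals
        ``eigenvalues_[k]``.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y=None):
        df = _as_frame(X)
        if self.standardize:
            Z = standardize(df)
        else:
            Z = df - df.mean()
        n, p = Z.shape
        cov = Z.to_numpy().T @ Z.to_numpy() / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        for k in range(p):
            j = np.argmax(np.abs(evecs[:, k]))
            if evecs[j, k] < 0:
                evecs[:, k] = -evecs[:, k]
        axes = [f"PC{k + 1}" for k in range(p)]
        self.n_samples_ = n
        self.columns_ = list(df.columns)
        self.mean_ = df.mean()
        self.scale_ = df.std(ddof=1) if self.standardize else None
        self.eigenvalues_ = evals
        self.rank_deficient_ = bool(np.any(evals < 1e-12))
        self.variance_explained_pct_ = 100.0 * evals / evals.sum()
        self.loadings_ = pd.DataFrame(evecs, index=self.columns_, columns=axes)
        self.contributions_pct_ = 100.0 * self.loadings_ ** 2
        self.scores_ = pd.DataFrame(Z.to_numpy() @ evecs, index=df.index,
                                    columns=axes)
        return self

    def transform(self, X) -> pd.DataFrame:
        df = _as_frame(X)[self.columns_]
        Z = df - self.mean_
        if self.standardize:
            Z = Z / self.scale_
        return pd.DataFrame(Z.to_numpy() @ self.loadings_.to_numpy(),
                            index=df.index, columns=self.loadings_.columns)


def fit_pca(z_table, standardize_input: bool = False) -> SwarmSpacePCA:
    """Fit :class:`SwarmSpacePCA` on an (already standardized) metric table."""
    return SwarmSpacePCA(standardize=standardize_input).fit(z_table)


def filter_metrics(pca: SwarmSpacePCA, n_axes: int = 3,
                   min_contribution_pct: float | None = None) -> tuple[list, list]:
    """Flag metrics that contribute little to the leading axes.

    A metric is flagged when its maximum contribution over the first
    ``n_axes`` axes falls below ``min_contribution_pct`` (default: the
    uniform-contribution reference 100/p). Returns (retained, excluded).
    """
    contrib = pca.contributions_pct_.iloc[:, :n_axes]
    if min_contribution_pct is None:
        min_contribution_pct = 100.0 / len(pca.columns_)
    flagged = contrib.max(axis=1) < min_contribution_pct
    retained = [m for m in pca.columns_ if not flagged[m]]
    excluded = [m for m in pca.columns_ if flagged[m]]
    if not retained:
        raise ValueError("all metrics excluded; lower min_contribution_pct")
    return retained, excluded


@dataclass
class TSNEResult:
    embedding: pd.DataFrame
    perplexity: float
    n_iter: int
    seed: int
    params: dict


class SwarmSpaceTSNE(BaseEstimator):
    """2-D t-SNE of the standardized metric table.

    Defaults follow the long-run settings used for event data: perplexity 10
    and 10000 gradient-descent iterations; deterministic for a given seed.
    Requires at least ``3 * perplexity`` rows.
    """

    def __init__(self, perplexity: float = 10.0, n_iter: int = 10_000,
                 seed: int = 0):
        self.perplexity = perplexity
        self.n_iter = n_iter
        self.seed = seed

    def fit(self, X, y=None):
        df = _as_frame(X)
        if len(df) < 3 * self.perplexity:
            raise ValueError(
                f"t-SNE with perplexity {self.perplexity} needs at least "
                f"{int(3 * self.perplexity)} rows, got {len(df)}")
        tsne = TSNE(n_components=2, perplexity=self.perplexity,
                    max_iter=self.n_iter, random_state=self.seed, init="pca")
        emb = tsne.fit_transform(df.to_numpy())
        self.embedding_ = pd.DataFrame(emb, index=df.index,
                                       columns=["dim1", "dim2"])
        self.params_ = {"perplexity": self.perplexity, "n_iter": self.n_iter,
                        "seed": self.seed,
                        "learning_rate": tsne.learning_rate_,
                        "early_exaggeration": tsne.early_exaggeration,
                        "kl_divergence": float(tsne.kl_divergence_)}
        return self


def fit_tsne(z_table, perplexity: float = 10.0, n_iter: int = 10_000,
             seed: int = 0) -> TSNEResult:
    """Functional wrapper over :class:`SwarmSpaceTSNE`."""
    est = SwarmSpaceTSNE(perplexity=perplexity, n_iter=n_iter, seed=seed).fit(z_table)
    return TSNEResult(embedding=est.embedding_, perplexity=perplexity,
                      n_iter=n_iter, seed=seed, params=est.params_)


def build_swarm_space(metric_table: pd.DataFrame,
                      metrics: list | None = None, n_axes: int = 3,
                      min_contribution_pct: float | None = None,
                      tsne_perplexity: float = 10.0, tsne_iter: int = 10_000,
                      seed: int = 0, run_tsne: bool = True) -> dict:
    """Full swarm-space construction from an event metric table.

    Standardizes the chosen metrics, fits the PCA, drops metrics whose
    contribution to the first ``n_axes`` axes is negligible, refits on the
    retained set, and (optionally) adds the t-SNE embedding. Returns a dict
    with keys ``pca`` (refit), ``pca_initial``, ``retained``, ``excluded``
    and ``tsne`` (None when skipped or infeasible).
    """
    metrics = list(metrics) if metrics is not None else [
        m for m in DEFAULT_SWARM_METRICS if m in metric_table.columns]
    table = metric_table[metrics]
    pca0 = SwarmSpacePCA().fit(table)
    retained, excluded = filter_metrics(pca0, n_axes, min_contribution_pct)
    pca = SwarmSpacePCA().fit(table[retained]) if excluded else pca0
    tsne = None
    if run_tsne and len(table) >= 3 * tsne_perplexity:
        tsne = fit_tsne(standardize(table[retained]), tsne_perplexity,
                        tsne_iter, seed)
    return {"pca": pca, "pca_initial": pca0, "retained": retained,
            "excluded": excluded, "tsne": tsne}
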