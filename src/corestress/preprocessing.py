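"""Expression preprocessing: log transform, filtering, ComBat, PCA, z-scores.

Matrices are pandas DataFrames with genes as rows and samples as columns
(the layout the TSV writers use). The :class:`ComBat` estimator follows the
scikit-learn transformer convention internally (samples x features) and is
wrapped by :func:`combat_adjust` for the genes x samples layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SKPCA
from sklearn.utils.validation import check_is_fitted


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Entrywise ``log2(x + 1)`` of a non-negative TPM matrix."""
    values = m.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative TPM")
    return pd.DataFrame(np.log2(values + 1.0), index=m.index, columns=m.columns)


def filter_zero_variance(m: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose values are constant across all samples.

    Row order of the surviving genes is preserved. An all-constant matrix
    yields an empty result with a warning rather than an error.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to assess variance")
    values = m.to_numpy(dtype=float)
    # max-min instead of var: exactly-constant rows must not survive on
    # floating-point rounding of the variance
    keep = values.max(axis=1) - values.min(axis=1) > 0
    if not keep.any():
        warnings.warn("all genes have zero variance; result is empty", stacklevel=2)
    return m.loc[keep]


class ComBat(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes batch correction (ComBat).

    Models each feature in batch ``b`` as
    ``x = alpha + gamma_b + delta_b * eps`` and shrinks the per-batch
    location (``gamma``) and scale (``delta``) estimates toward pooled
    priors before removing them. No covariates are used: the only design
    variable is the batch label, which keeps the model identifiable when
    treatment labels are unbalanced across batches.

    Parameters
    ----------
    conv:
        Convergence tolerance of the EB fixed-point iteration.

    Attributes
    ----------
    batches_ : list
        Batch labels in fitting order.
    gamma_star_, delta_star_ : ndarray (n_batches, n_features)
        Shrunken batch location/scale estimates on the standardized scale.
    grand_mean_ : ndarray (n_features,)
        Sample-size weighted cross-batch feature mean.
    var_pooled_ : ndarray (n_features,)
        Pooled residual variance after removing batch means.

    Notes
    -----
    ``fit`` expects samples x features with a per-sample ``batch`` array, on
    already log-transformed data. A single-batch input is returned
    unchanged (there is nothing to correct; the standardize/back-transform
    round trip is the identity).
    """

    def __init__(self, conv: float = 1e-4, max_iter: int = 500):
        self.conv = conv
        self.max_iter = max_iter

    def fit(self, X, y=None, *, batch=None):
        self.fit_transform(X, y, batch=batch)
        return self

    def fit_transform(self, X, y=None, *, batch=None):
        if batch is None:
            raise ValueError("ComBat requires a per-sample `batch` array")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if len(batch) != X.shape[0]:
            raise ValueError("batch length must equal the number of samples")

        levels = list(pd.unique(batch))
        counts = {b: int(np.sum(batch == b)) for b in levels}
        for b, n in counts.items():
            if n < 2:
                raise ValueError(f"batch {b!r} has {n} sample(s); ComBat needs >= 2 per batch")

        self.batches_ = levels
        self.n_features_in_ = X.shape[1]
        if len(levels) == 1:
            self.gamma_star_ = np.zeros((1, X.shape[1]))
            self.delta_star_ = np.ones((1, X.shape[1]))
            self.grand_mean_ = X.mean(axis=0)
            self.var_pooled_ = X.var(axis=0)
            self._single_batch = True
            return X.copy()
        self._single_batch = False

        n_total = X.shape[0]
        masks = [batch == b for b in levels]
        n_b = np.array([m.sum() for m in masks], dtype=float)

        batch_means = np.stack([X[m].mean(axis=0) for m in masks])  # (B, G)
        grand_mean = (n_b / n_total) @ batch_means
        fitted = np.zeros_like(X)
        for m, bm in zip(masks, batch_means):
            fitted[m] = bm
        var_pooled = ((X - fitted) ** 2).sum(axis=0) / n_total

        degenerate = var_pooled <= 0  # constant within every batch
        safe_var = np.where(degenerate, 1.0, var_pooled)

        s_data = (X - grand_mean) / np.sqrt(safe_var)

        gamma_hat = np.stack([s_data[m].mean(axis=0) for m in masks])
        delta_hat = np.stack([s_data[m].var(axis=0, ddof=1) for m in masks])

        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        a_prior = np.array([self._aprior(d) for d in delta_hat])
        b_prior = np.array([self._bprior(d) for d in delta_hat])

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, m in enumerate(masks):
            g, d = self._it_sol(
                s_data[m],
                gamma_hat[i],
                delta_hat[i],
                gamma_bar[i],
                tau2[i],
                a_prior[i],
                b_prior[i],
            )
            gamma_star[i] = g
            delta_star[i] = d

        adjusted = s_data.copy()
        for i, m in enumerate(masks):
            adjusted[m] = (s_data[m] - gamma_star[i]) / np.sqrt(delta_star[i])
        adjusted = adjusted * np.sqrt(safe_var) + grand_mean
        adjusted[:, degenerate] = X[:, degenerate]

        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.grand_mean_ = grand_mean
        self.var_pooled_ = var_pooled
        return adjusted

    def transform(self, X, *, batch=None):
        # ComBat is a fit-on-the-data correction; transform on the fitted
        # data is fit_transform. For new data, refit.
        check_is_fitted(self, "gamma_star_")
        raise NotImplementedError(
            "ComBat adjusts the data it was fit on; use fit_transform"
        )

    @staticmethod
    def _aprior(delta_hat: np.ndarray) -> float:
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        return (2 * s2 + m**2) / s2

    @staticmethod
    def _bprior(delta_hat: np.ndarray) -> float:
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        return (m * s2 + m**3) / s2

    def _it_sol(self, s_batch, g_hat, d_hat, g_bar, t2, a, b):
        n = s_batch.shape[0]
        g_old, d_old = g_hat.copy(), d_hat.copy()
        for _ in range(self.max_iter):
            g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
            sum2 = ((s_batch - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
                np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < self.conv:
                break
        return g_old, d_old


def combat_adjust(m: pd.DataFrame, batches: pd.Series | np.ndarray) -> pd.DataFrame:
    """Batch-correct a genes x samples log-expression matrix.

    ``batches`` gives the BioProject of each sample (aligned with the
    columns of ``m``, or a Series indexed by sample id).
    """
    if isinstance(batches, pd.Series):
        batches = batches.reindex(m.columns)
        if batches.isna().any():
            missing = list(m.columns[batches.isna()])
            raise ValueError(f"samples missing batch labels: {missing[:5]}")
        batches = batches.to_numpy()
    adjusted = ComBat().fit_transform(m.to_numpy(dtype=float).T, batch=batches)
    return pd.DataFrame(adjusted.T, index=m.index, columns=m.columns)


@dataclass
class PCAResult:
    """Centered PCA of samples with a fixed sign convention."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fraction per component
    components: pd.DataFrame  # components x genes (loadings)


def pca(m: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Centered PCA of samples on a genes x samples matrix.

    No variance scaling is applied (log-TPM is used directly). The sign of
    each component is fixed so that its largest-magnitude gene loading is
    positive, making scores reproducible across library versions.
    """
    X = m.to_numpy(dtype=float).T  # samples x genes
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_genes)={min(X.shape)}"
        )
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    components = model.components_
    for k in range(n_components):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.columns, columns=cols),
        variance_explained=model.explained_variance_ratio_.copy(),
        components=pd.DataFrame(components, index=cols, columns=m.index),
    )


def zscore_genes(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene to mean 0, sd 1 across samples.

    The population standard deviation (divide by n) is used; this is the
    fixed convention throughout the package and makes the operation
    idempotent.
    """
    values = m.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # ddof=0
    if np.any(sd == 0):
        bad = list(m.index[(sd == 0).ravel()])
        raise ValueError(f"zero-variance genes cannot be z-scored: {bad[:5]}")
    return pd.DataFrame((values - mean) / sd, index=m.index, columns=m.columns)


@dataclass
class TreatmentTree:
    """Hierarchical clustering of per-treatment mean expression profiles."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy linkage encoding
    mean_profiles: pd.DataFrame  # treatments x genes

    @property
    def n_merges(self) -> int:
        return self.linkage_matrix.shape[0]


def treatment_dendrogram(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    metric: str = "euclidean",
    method: str = "average",
) -> TreatmentTree:
    """Cluster treatments by their mean (z-scored, corrected) profiles.

    One mean profile is computed per treatment over all its samples; the
    profiles are then agglomeratively clustered. Treatments with no sample
    present in the matrix are excluded with a warning. Linkage and metric
    default to average/Euclidean and are configurable.
    """
    treatments = meta.loc[m.columns, "treatment"]
    present = treatments.value_counts()
    declared = set(meta["treatment"].unique())
    missing = declared - set(present.index)
    if missing:
        warnings.warn(
            f"treatments with no samples excluded from dendrogram: {sorted(missing)}",
            stacklevel=2,
        )
    labels = sorted(present.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 treatments to cluster")
    profiles = pd.DataFrame(
        {t: m.loc[:, treatments[treatments == t].index].mean(axis=1) for t in labels}
    ).T
    Z = linkage(pdist(profiles.to_numpy(), metric=metric), method=method)
    return TreatmentTree(labels=labels, linkage_matrix=Z, mean_profiles=profiles)
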