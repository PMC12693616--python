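"""Hold-one-stressor-out random-forest classification and core-gene selection.

Six binary stress-vs-control classifiers are trained, each with every
sample (stressed and control) of one stressor's experiments held out as the
test set. Because the test stressor is absent from training, good held-out
performance can only come from expression signatures shared across
stressors; the most important features of each model are candidate core
stress-responsive genes, and the intersection of the six top-k importance
sets is the random-forest core set.

Training folds are SMOTE-balanced after the split (synthetic minority
samples are interpolations between minority neighbors); the test set is
never resampled or otherwise touched before evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from corestress.tn_ratio import bioproject_stressors

#: Feature-subset sizes evaluated during iterative feature selection.
DEFAULT_SUBSET_SIZES: tuple[int, ...] = (
    50, 100, 250, 500, 1000, 1500, 2000, 2500, 3000,
    4000, 5000, 6000, 7000, 8000, 10000, 15000,
)

#: Hyperparameter grid: bootstrapping, tree depth, feature sampling,
#: leaf/split sizes and forest size.
DEFAULT_PARAM_GRID: dict[str, list] = {
    "bootstrap": [True, False],
    "max_depth": [None, 10, 20, 40],
    "max_features": ["sqrt", "log2", 0.1],
    "min_samples_leaf": [1, 2, 4],
    "min_samples_split": [2, 5, 10],
    "n_estimators": [100, 200],
}


class SMOTE:
    """Synthetic minority oversampling (interpolation between neighbors).

    New minority samples are convex combinations ``x_i + u * (x_j - x_i)``
    of a minority sample and one of its ``k_neighbors`` nearest minority
    neighbors, ``u ~ Uniform(0, 1)``. Originals are always retained and the
    classes are exactly balanced on output.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("SMOTE requires both classes in the training data")
        if len(classes) > 2:
            raise ValueError("only binary labels are supported")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        n_new = int(n_maj - n_min)
        if n_new == 0:
            return X.copy(), y.copy()
        if n_min < 2:
            raise ValueError("minority class needs >= 2 samples for interpolation")
        k = self.k_neighbors
        if n_min <= k:
            k = n_min - 1
            warnings.warn(
                f"minority class has {n_min} samples; reducing k_neighbors to {k}",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        X_min = X[y == minority]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)  # column 0 is the sample itself
        base = rng.integers(0, n_min, size=n_new)
        neigh = idx[base, rng.integers(1, k + 1, size=n_new)]
        u = rng.random(size=(n_new, 1))
        X_new = X_min[base] + u * (X_min[neigh] - X_min[base])
        X_out = np.vstack([X, X_new])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


def smote_balance(X, y, k_neighbors: int = 5, random_state: int | None = None):
    """Functional wrapper over :class:`SMOTE`."""
    return SMOTE(k_neighbors=k_neighbors, random_state=random_state).fit_resample(X, y)


def split_hold_one_stressor(meta: pd.DataFrame, stressor: str) -> tuple[list[str], list[str]]:
    """Hold out all samples (stressed and control) of one stressor's BioProjects.

    Returns (train sample ids, test sample ids); the two lists partition
    all samples.
    """
    bp_stress = bioproject_stressors(meta)
    if stressor not in set(bp_stress.values()):
        raise ValueError(f"stressor {stressor!r} not present in the metadata")
    test_bps = {bp for bp, s in bp_stress.items() if s == stressor}
    is_test = meta["bioproject"].isin(test_bps)
    return list(meta.index[~is_test]), list(meta.index[is_test])


@dataclass
class RFConfig:
    """Tuning and feature-selection settings for the hold-one-out models."""

    param_grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_PARAM_GRID))
    n_iter: int = 10  # randomized-search budget per model
    cv: int = 3
    subset_sizes: tuple[int, ...] = DEFAULT_SUBSET_SIZES
    top_k: int = 6000
    smote_k: int = 5
    auc_tolerance: float = 0.01  # "near-optimal" band for the smallest subset
    importance_trees: int = 500  # floor on trees in the final refit (stable rankings)
    n_jobs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.subset_sizes = tuple(self.subset_sizes)
        if list(self.subset_sizes) != sorted(set(self.subset_sizes)):
            raise ValueError("subset_sizes must be strictly increasing")


@dataclass
class RFRunResult:
    """Outcome of one held-out-stressor model."""

    held_out_stressor: str
    best_params: dict
    metrics: dict[str, float | None]  # accuracy, auc, f1 on the held-out test set
    importances: pd.Series  # per gene, >= 0, sums to 1
    feature_curve: pd.DataFrame | None = None  # subset_size x metrics
    optimal_subset_size: int | None = None


def _fit_rf(X, y, params: dict, seed: int, n_jobs: int) -> RandomForestClassifier:
    model = RandomForestClassifier(random_state=seed, n_jobs=n_jobs, **params)
    model.fit(X, y)
    return model


def _evaluate(model: RandomForestClassifier, X_test, y_test) -> dict[str, float | None]:
    pred = model.predict(X_test)
    out: dict[str, float | None] = {
        "accuracy": float(accuracy_score(y_test, pred)),
        "f1": float(f1_score(y_test, pred)),
    }
    if len(np.unique(y_test)) < 2:
        warnings.warn("test set has one class; AUC undefined", stacklevel=3)
        out["auc"] = None
    else:
        proba = model.predict_proba(X_test)[:, list(model.classes_).index(1)]
        out["auc"] = float(roc_auc_score(y_test, proba))
    return out


def tune_fit_evaluate(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    config: RFConfig,
    seed: int,
    held_out_stressor: str = "",
) -> RFRunResult:
    """Randomized hyperparameter search, final fit, held-out evaluation.

    The search uses stratified k-fold CV on the training set only, with
    SMOTE applied inside each fold (never to validation or test data). The
    best configuration by mean validation AUC is refit on the full
    SMOTE-balanced training set and evaluated once on the untouched test
    set. Importances are sklearn's impurity-based feature importances,
    which are non-negative and sum to 1; the final refit raises the tree
    count to at least ``config.importance_trees`` because importance
    *rankings* from small forests are noisy even when the classification
    metrics have converged.
    """
    genes = list(X_train.columns)
    Xtr = X_train.to_numpy(dtype=float)
    ytr = np.asarray(y_train).astype(int)
    rng = np.random.RandomState(seed)

    candidates = list(ParameterSampler(config.param_grid, n_iter=config.n_iter, random_state=rng))
    skf = StratifiedKFold(n_splits=config.cv, shuffle=True, random_state=seed)
    folds = list(skf.split(Xtr, ytr))
    best_params, best_score = candidates[0], -np.inf
    for params in candidates:
        scores = []
        for tr_idx, va_idx in folds:
            Xb, yb = smote_balance(Xtr[tr_idx], ytr[tr_idx], config.smote_k, random_state=seed)
            model = _fit_rf(Xb, yb, params, seed, config.n_jobs)
            if len(np.unique(ytr[va_idx])) < 2:
                continue
            proba = model.predict_proba(Xtr[va_idx])[:, list(model.classes_).index(1)]
            scores.append(roc_auc_score(ytr[va_idx], proba))
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score:
            best_score, best_params = mean, params

    Xb, yb = smote_balance(Xtr, ytr, config.smote_k, random_state=seed)
    final_params = dict(best_params)
    final_params["n_estimators"] = max(
        final_params.get("n_estimators", 100), config.importance_trees
    )
    model = _fit_rf(Xb, yb, final_params, seed, config.n_jobs)
    metrics = _evaluate(model, X_test.to_numpy(dtype=float), np.asarray(y_test).astype(int))
    imp = model.feature_importances_.astype(float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    importances = pd.Series(imp, index=genes, name="importance")
    return RFRunResult(
        held_out_stressor=held_out_stressor,
        best_params=dict(best_params),
        metrics=metrics,
        importances=importances,
    )


def rank_genes(importances: pd.Series) -> list[str]:
    """Genes ordered by decreasing importance, ties broken by gene id."""
    df = importances.rename_axis("gene").reset_index(name="imp")
    df = df.sort_values(["imp", "gene"], ascending=[False, True], kind="stable")
    return list(df["gene"])


def iterative_feature_selection(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    importances: pd.Series,
    subset_sizes: tuple[int, ...],
    params: dict,
    seed: int,
    smote_k: int = 5,
    auc_tolerance: float = 0.01,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, int | None]:
    """Refit on top-X gene subsets and locate the smallest near-optimal X.

    For every subset size X (sizes exceeding the gene count are skipped
    with a warning) the model is refit on the top-X most important genes
    and scored on the test set. The optimum is the smallest X whose AUC is
    within ``auc_tolerance`` of the best AUC over all sizes.
    """
    ranked = rank_genes(importances)
    rows = []
    ytr = np.asarray(y_train).astype(int)
    yte = np.asarray(y_test).astype(int)
    for size in subset_sizes:
        if size > len(ranked):
            warnings.warn(f"subset size {size} exceeds gene count {len(ranked)}; skipped", stacklevel=2)
            continue
        top = ranked[:size]
        Xb, yb = smote_balance(X_train.loc[:, top].to_numpy(dtype=float), ytr, smote_k, random_state=seed)
        model = _fit_rf(Xb, yb, params, seed, n_jobs)
        metrics = _evaluate(model, X_test.loc[:, top].to_numpy(dtype=float), yte)
        rows.append({"subset_size": size, **metrics})
    curve = pd.DataFrame(rows).set_index("subset_size") if rows else pd.DataFrame()
    optimal = None
    if len(curve) and curve["auc"].notna().any():
        best = curve["auc"].max()
        ok = curve.index[curve["auc"] >= best - auc_tolerance]
        optimal = int(ok.min())
    return curve, optimal


def rf_core_genes(
    results: dict[str, RFRunResult],
    top_k: int = 6000,
    expected_stressors: tuple[str, ...] | None = None,
    allow_partial: bool = False,
) -> set[str]:
    """Intersection of the per-model top-k most important genes.

    Rank ties at the boundary are broken by gene id (stable). By default
    every expected stressor must have a result; pass ``allow_partial`` to
    intersect over whichever models are present.
    """
    if expected_stressors is not None:
        missing = set(expected_stressors) - set(results)
        if missing and not allow_partial:
            raise ValueError(f"missing models for stressors: {sorted(missing)}")
    if not results:
        raise ValueError("no model results provided")
    tops = [set(rank_genes(r.importances)[:top_k]) for r in results.values()]
    return set.intersection(*tops)


def annotate_direction(
    core: set[str], per_stressor: dict[str, dict[str, set[str]]]
) -> dict[str, int]:
    """Cross-reference a core set against TN-ratio direction calls.

    A gene counts as up if it is up-called under at least one stressor and
    as down if down-called under at least one (possibly both, so
    up + down + none can exceed the set size); genes never called are
    ``none``.
    """
    any_up = set().union(*(d["up"] for d in per_stressor.values()))
    any_down = set().union(*(d["down"] for d in per_stressor.values()))
    up = len(core & any_up)
    down = len(core & any_down)
    none = len(core - any_up - any_down)
    return {"up": up, "down": down, "none": none, "total": len(core)}


class HoldOneStressorOutRF(BaseEstimator):
    """Estimator running the full hold-one-stressor-out analysis.

    Parameters mirror :class:`RFConfig`. ``fit`` takes the batch-corrected
    log2 expression matrix (genes x samples) and the sample metadata and
    fits one tuned model per stressor with that stressor's experiments held
    out.

    Attributes
    ----------
    results_ : dict
        stressor -> :class:`RFRunResult`.
    core_genes_ : set
        Intersection of the per-model top-``top_k`` importance sets.
    """

    def __init__(
        self,
        n_iter: int = 10,
        cv: int = 3,
        top_k: int = 6000,
        subset_sizes: tuple[int, ...] = DEFAULT_SUBSET_SIZES,
        run_feature_curve: bool = False,
        smote_k: int = 5,
        importance_trees: int = 500,
        n_jobs: int = 1,
        seed: int = 0,
    ):
        self.n_iter = n_iter
        self.cv = cv
        self.top_k = top_k
        self.subset_sizes = subset_sizes
        self.run_feature_curve = run_feature_curve
        self.smote_k = smote_k
        self.importance_trees = importance_trees
        self.n_jobs = n_jobs
        self.seed = seed

    def _config(self) -> RFConfig:
        return RFConfig(
            n_iter=self.n_iter,
            cv=self.cv,
            subset_sizes=tuple(self.subset_sizes),
            top_k=self.top_k,
            smote_k=self.smote_k,
            importance_trees=self.importance_trees,
            n_jobs=self.n_jobs,
            seed=self.seed,
        )

    def fit(self, m: pd.DataFrame, meta: pd.DataFrame):
        config = self._config()
        stressors = sorted(set(bioproject_stressors(meta).values()))
        X_all = m.T  # samples x genes
        labels = (meta.loc[X_all.index, "treatment"] != "control").astype(int)
        results: dict[str, RFRunResult] = {}
        for i, stressor in enumerate(stressors):
            train_ids, test_ids = split_hold_one_stressor(meta, stressor)
            seed = (self.seed + 7919 * (i + 1)) % (2**31)
            result = tune_fit_evaluate(
                X_all.loc[train_ids],
                labels.loc[train_ids].to_numpy(),
                X_all.loc[test_ids],
                labels.loc[test_ids].to_numpy(),
                config,
                seed=seed,
                held_out_stressor=stressor,
            )
            if self.run_feature_curve:
                curve, optimal = iterative_feature_selection(
                    X_all.loc[train_ids],
                    labels.loc[train_ids].to_numpy(),
                    X_all.loc[test_ids],
                    labels.loc[test_ids].to_numpy(),
                    result.importances,
                    config.subset_sizes,
                    result.best_params,
                    seed=seed,
                    smote_k=config.smote_k,
                    auc_tolerance=config.auc_tolerance,
                    n_jobs=config.n_jobs,
                )
                result.feature_curve = curve
                result.optimal_subset_size = optimal
            results[stressor] = result
        self.results_ = results
        self.stressors_ = stressors
        self.core_genes_ = rf_core_genes(results, top_k=self.top_k)
        return self
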