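"""Random-forest regulatory-network inference and Dunnett weight comparisons.

For every target gene a random-forest regressor predicts its expression
from all transcription-factor expressions (a TF never predicts itself); the
impurity-reduction importance of each TF is the weight of the directed
TF -> target edge. Per target, weights sum to 1 (sklearn's importance
normalization), so weights are comparable across targets.

To ask whether a set of focal TFs preferentially regulates particular gene
classes (core, per-stressor specific, other), each target's mean incoming
weight from the focal TFs is compared across classes with Dunnett's
many-to-one test against the "other" class. Dunnett's test on fixed data is
deterministic, so a p-value *distribution* is built by bootstrap-resampling
targets within each class and re-testing (default 5,000 repetitions); a
comparison is significant when the upper bound of the 95% interval
(2.5th-97.5th percentiles) of its p-value distribution is below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor


class GENIE3(BaseEstimator):
    """Random-forest gene-regulatory-network inference.

    Parameters
    ----------
    n_trees:
        Trees per per-target forest (100 keeps desk-scale runtimes).
    max_features:
        Fraction/number of candidate TFs per split (random-forest style
        feature subsampling; ``"sqrt"`` by default).
    seed:
        Controls every per-target forest; a fixed seed gives a bit-identical
        edge list.

    Attributes
    ----------
    edges_ : pandas.DataFrame
        Directed weighted edge list with columns
        ``regulator``, ``target``, ``weight`` (complete TF x gene bipartite
        graph minus self-edges).
    weight_matrix_ : pandas.DataFrame
        targets x regulators weight matrix (same information as edges_).
    """

    def __init__(self, n_trees: int = 100, max_features="sqrt", seed: int = 0, n_jobs: int = 1):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.n_jobs = n_jobs

    def fit(self, m: pd.DataFrame, tf_list: list[str], y=None):
        """Infer the network from a corrected log-TPM genes x samples matrix."""
        tfs = [t for t in tf_list if t in m.index]
        if len(tfs) < 2:
            raise ValueError("need at least 2 TFs present in the expression matrix")
        if m.shape[1] < 10:
            raise ValueError("need at least 10 samples for GRN inference")
        X_tf = m.loc[tfs].to_numpy(dtype=float).T  # samples x TFs
        tf_pos = {t: i for i, t in enumerate(tfs)}

        targets = list(m.index)
        weights = np.zeros((len(targets), len(tfs)))
        ss = np.random.SeedSequence(self.seed)
        child_seeds = ss.generate_state(len(targets)) % (2**31)
        for row, target in enumerate(targets):
            y_t = m.loc[target].to_numpy(dtype=float)
            sd = y_t.std()
            if sd == 0:
                warnings.warn(f"target {target!r} has zero variance; weights set to 0", stacklevel=2)
                continue
            y_t = (y_t - y_t.mean()) / sd
            if target in tf_pos:
                cols = [i for i in range(len(tfs)) if i != tf_pos[target]]
            else:
                cols = list(range(len(tfs)))
            if not cols:
                continue
            model = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=self.max_features,
                random_state=int(child_seeds[row]),
                n_jobs=self.n_jobs,
            )
            model.fit(X_tf[:, cols], y_t)
            weights[row, cols] = model.feature_importances_

        self.weight_matrix_ = pd.DataFrame(weights, index=pd.Index(targets, name="target"), columns=tfs)
        edges = self.weight_matrix_.stack().rename("weight").reset_index()
        edges.columns = ["target", "regulator", "weight"]
        edges = edges[edges["target"] != edges["regulator"]]
        self.edges_ = edges[["regulator", "target", "weight"]].reset_index(drop=True)
        return self


def infer_grn(
    m: pd.DataFrame,
    tf_list: list[str],
    seed: int = 0,
    n_trees: int = 100,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Functional wrapper over :class:`GENIE3`; returns the edge list."""
    return GENIE3(n_trees=n_trees, seed=seed, n_jobs=n_jobs).fit(m, tf_list).edges_


def mean_incoming_weight(
    edges: pd.DataFrame,
    focal_tfs: set[str],
    targets: list[str] | None = None,
) -> pd.Series:
    """Per-target mean regulatory weight from a set of focal TFs.

    Targets that receive no edge from any focal TF are excluded; the count
    of exclusions is reported as a warning. Non-focal edges never enter the
    mean.
    """
    focal_tfs = set(focal_tfs)
    regulators = set(edges["regulator"])
    if not focal_tfs <= regulators:
        raise ValueError(f"focal TFs missing from the edge list: {sorted(focal_tfs - regulators)[:5]}")
    sub = edges[edges["regulator"].isin(focal_tfs)]
    means = sub.groupby("target", sort=True)["weight"].mean()
    if targets is not None:
        wanted = pd.Index(targets)
        dropped = len(wanted.difference(means.index))
        if dropped:
            warnings.warn(f"{dropped} target(s) with no focal incoming edges excluded", stacklevel=2)
        means = means.loc[means.index.intersection(wanted)]
    means.name = "mean_weight"
    return means


def dunnett_compare(
    values: pd.Series,
    groups: dict[str, list[str]],
    control: str = "other",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparison of group means against a control group.

    Classical pooled-variance Dunnett test: each non-control group is
    compared with the control and the family-wise adjustment uses the joint
    multivariate-t distribution of the contrast statistics. Groups with
    fewer than 2 members are dropped with a warning. Returns one row per
    non-control group with the group mean, the difference from control, the
    t statistic and the adjusted p-value.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    usable: dict[str, np.ndarray] = {}
    for name, ids in groups.items():
        vals = values.loc[[i for i in ids if i in values.index]].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has <2 members and was dropped", stacklevel=2)
            continue
        usable[name] = vals
    if control not in usable:
        raise ValueError("control group has fewer than 2 usable members")
    treat_names = [n for n in usable if n != control]
    if not treat_names:
        raise ValueError("no non-control group with >= 2 members")
    with warnings.catch_warnings():
        # near-identical weights (e.g. many zero-weight targets) trigger a
        # benign precision-loss RuntimeWarning in scipy's moment computation
        warnings.filterwarnings("ignore", category=RuntimeWarning, message=".*[Pp]recision loss.*")
        res = stats.dunnett(
            *(usable[n] for n in treat_names),
            control=usable[control],
            random_state=np.random.default_rng(seed),
        )
    pvalues = np.atleast_1d(res.pvalue).astype(float)
    if len(treat_names) == 1:
        # single contrast: Dunnett degenerates to the pooled two-sample
        # two-sided t-test, which has a closed form (no QMC error)
        df = len(usable[control]) + len(usable[treat_names[0]]) - 2
        stat = float(np.atleast_1d(res.statistic)[0])
        pvalues = np.array([2.0 * stats.t.sf(abs(stat), df)])
    control_mean = float(usable[control].mean())
    return pd.DataFrame(
        {
            "group": treat_names,
            "n": [len(usable[n]) for n in treat_names],
            "mean": [float(usable[n].mean()) for n in treat_names],
            "diff_from_control": [float(usable[n].mean()) - control_mean for n in treat_names],
            "statistic": np.atleast_1d(res.statistic),
            "p": pvalues,
        }
    )


@dataclass
class DunnettResult:
    """Repeated-Dunnett outcome for one comparison family."""

    table: pd.DataFrame  # group, n, mean, diff_from_control, observed p, CI, significant
    control: str
    n_reps: int

    def significant_groups(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "group"])


def repeated_dunnett(
    values: pd.Series,
    group_sets: dict[str, list[str]],
    control: str = "other",
    n_reps: int = 5000,
    seed: int = 0,
) -> DunnettResult:
    """Bootstrap-repeated Dunnett test yielding a p-value distribution.

    Dunnett's test on fixed inputs is deterministic, so repetitions
    resample targets within each group (with replacement, original sizes)
    and re-test; the per-group 2.5th-97.5th percentile interval of the
    resulting p values is reported, and a group is significant when the
    interval's upper bound is below 0.05. The observed means carry the sign
    of the effect: a significant group may have a *lower* mean weight than
    the control.
    """
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} gives an unstable CI; use >= 100", stacklevel=2)
    observed = dunnett_compare(values, group_sets, control=control, seed=seed)
    rng = np.random.default_rng(seed)
    group_values = {
        name: values.loc[[i for i in ids if i in values.index]].to_numpy(dtype=float)
        for name, ids in group_sets.items()
    }
    group_values = {n: v for n, v in group_values.items() if len(v) >= 2}
    treat_names = list(observed["group"])
    pvals = np.empty((n_reps, len(treat_names)))
    with warnings.catch_warnings():
        # bootstrap resamples with many tied values trigger a benign
        # precision-loss RuntimeWarning inside scipy's moment computation
        warnings.filterwarnings("ignore", category=RuntimeWarning, message=".*[Pp]recision loss.*")
        for r in range(n_reps):
            boot = {n: rng.choice(v, size=len(v), replace=True) for n, v in group_values.items()}
            res = stats.dunnett(
                *(boot[n] for n in treat_names),
                control=boot[control],
                random_state=rng,
            )
            pvals[r] = np.atleast_1d(res.pvalue)
    lo = np.percentile(pvals, 2.5, axis=0)
    hi = np.percentile(pvals, 97.5, axis=0)
    table = observed.copy()
    table["p_ci_low"] = lo
    table["p_ci_high"] = hi
    table["significant"] = hi < 0.05
    return DunnettResult(table=table, control=control, n_reps=n_reps)
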