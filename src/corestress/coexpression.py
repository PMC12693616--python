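"""Weighted co-expression network: adjacency, TOM modules, kME, hub genes.

The procedure follows the classical weighted co-expression recipe: a
soft-thresholded correlation adjacency (``|cor|^power`` unsigned, default
power 9), topological-overlap dissimilarity, average-linkage clustering cut
at a fixed height with a minimum module size, module eigengenes (first
principal component of each module), signed module membership
``kME(gene, module) = cor(gene, eigengene)``, and hub genes above the 95th
percentile of own-module |kME|. Unassigned genes form the background module
``M0``; real modules are labelled ``M1..`` by decreasing size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from corestress.enrichment import fdr_adjust, _classify, _counts_row, _fisher_counts


def build_adjacency(
    m: pd.DataFrame, power: int = 9, network_type: str = "unsigned"
) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency in [0, 1].

    Unsigned: ``|cor|^power``; signed: ``((1 + cor)/2)^power``. The
    diagonal is 1 by convention. Zero-variance genes must be filtered
    beforehand (their correlation is undefined).
    """
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples for co-expression")
    values = m.to_numpy(dtype=float)
    if np.any(values.var(axis=1) == 0):
        bad = list(m.index[values.var(axis=1) == 0])
        raise ValueError(f"zero-variance genes must be filtered first: {bad[:5]}")
    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    if network_type == "unsigned":
        adj = np.abs(cor) ** power
    elif network_type == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError("network_type must be 'unsigned' or 'signed'")
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=m.index, columns=m.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix of a co-expression adjacency."""
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


class CoexpressionNetwork(BaseEstimator):
    """Weighted co-expression network model.

    Parameters
    ----------
    power:
        Soft-thresholding exponent of the correlation matrix.
    network_type:
        ``"unsigned"`` (|cor|^power, the historical default) or
        ``"signed"``.
    min_module_size:
        Clusters smaller than this become background (M0).
    cut_height:
        Static cut height on the TOM-dissimilarity average-linkage tree.
    hub_percentile:
        Quantile of |own-module kME| defining the hub threshold
        (linear-interpolation / type-7 quantile).

    Attributes
    ----------
    modules_ : pandas.Series
        gene -> module label (``M0`` background, ``M1..`` by size).
    eigengenes_ : pandas.DataFrame
        module x sample eigengene profiles (non-background modules).
    kme_ : pandas.DataFrame
        gene x module signed membership correlations.
    hub_threshold_ : float
        Empirical ``hub_percentile`` quantile of assigned genes'
        |own-module kME|.
    hub_genes_ : set
        Genes with |own-module kME| strictly above the threshold.
    """

    def __init__(
        self,
        power: int = 9,
        network_type: str = "unsigned",
        min_module_size: int = 20,
        cut_height: float = 0.9,
        hub_percentile: float = 0.95,
    ):
        self.power = power
        self.network_type = network_type
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.hub_percentile = hub_percentile

    # -- stages, usable standalone -----------------------------------------
    def detect_modules(self, adjacency: pd.DataFrame) -> pd.Series:
        """Cluster the TOM dissimilarity and assign module labels."""
        genes = adjacency.index
        if len(genes) < self.min_module_size:
            warnings.warn("fewer genes than min_module_size; all genes in M0", stacklevel=2)
            return pd.Series("M0", index=genes, name="module")
        diss = 1.0 - topological_overlap(adjacency).to_numpy()
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        Z = linkage(squareform(diss, checks=False), method="average")
        raw = fcluster(Z, t=self.cut_height, criterion="distance")
        labels = pd.Series("M0", index=genes, name="module")
        sizes = pd.Series(raw).value_counts()
        kept = [c for c in sizes.index if sizes[c] >= self.min_module_size]
        # deterministic ordering: by decreasing size, then first occurrence
        first_pos = {c: int(np.argmax(raw == c)) for c in kept}
        kept.sort(key=lambda c: (-sizes[c], first_pos[c]))
        for rank, cluster in enumerate(kept, start=1):
            labels.iloc[np.where(raw == cluster)[0]] = f"M{rank}"
        return labels

    def module_eigengenes(self, m: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
        """First principal component per module, sign-oriented.

        Each module's genes are standardized (mean 0, sd 1 per gene); the
        eigengene is the leading right singular vector over samples,
        oriented to correlate positively with the module's mean profile.
        Singleton modules use the gene's standardized profile directly.
        """
        module_ids = sorted(set(modules) - {"M0"}, key=lambda x: int(x[1:]))
        rows = {}
        for mod in module_ids:
            genes = modules.index[modules == mod]
            X = m.loc[genes].to_numpy(dtype=float)
            Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
            if Xs.shape[0] == 1:
                eig = Xs[0]
            else:
                # first right singular vector of the gene-standardized module
                _, _, vt = np.linalg.svd(Xs, full_matrices=False)
                eig = vt[0]
                mean_profile = Xs.mean(axis=0)
                if np.corrcoef(eig, mean_profile)[0, 1] < 0:
                    eig = -eig
            rows[mod] = eig
        return pd.DataFrame(rows, index=m.columns).T

    def compute_kme(self, m: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
        """Signed module membership: cor(gene profile, module eigengene)."""
        X = m.to_numpy(dtype=float)
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        E = eigengenes.to_numpy(dtype=float)
        Es = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
        kme = (Xs @ Es.T) / X.shape[1]
        return pd.DataFrame(
            np.clip(kme, -1.0, 1.0), index=m.index, columns=eigengenes.index
        )

    def hub_genes(
        self, kme: pd.DataFrame, modules: pd.Series
    ) -> tuple[set[str], float]:
        """Hub genes: |own-module kME| above the percentile threshold.

        The threshold is the linear-interpolation quantile of assigned
        (non-M0) genes' absolute own-module kME; membership is strict
        (``>``), so an all-tied kME vector yields no hubs.
        """
        assigned = modules.index[modules != "M0"]
        if len(assigned) == 0:
            return set(), float("nan")
        own = np.array([abs(kme.at[g, modules[g]]) for g in assigned])
        threshold = float(np.quantile(own, self.hub_percentile))
        hubs = {g for g, v in zip(assigned, own) if v > threshold}
        return hubs, threshold

    def module_set_enrichment(
        self,
        modules: pd.Series,
        gene_set: set[str],
        universe: set[str] | None = None,
    ) -> pd.DataFrame:
        """Per-module one-sided Fisher enrichment of a gene set, with FDR.

        The universe defaults to all genes in the network. Modules
        (including M0) are each tested for containing more of the gene set
        than chance; q-values are BH-adjusted across modules.
        """
        universe = set(universe) if universe is not None else set(modules.index)
        gene_set = set(gene_set) & universe
        rows = []
        for mod in sorted(set(modules), key=lambda x: int(x[1:])):
            members = set(modules.index[modules == mod]) & universe
            a, b, c, d = _counts_row(members, gene_set, len(universe))
            odds, p = _fisher_counts(a, b, c, d)
            rows.append(
                {"module": mod, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p}
            )
        table = pd.DataFrame(rows)
        table["q"] = fdr_adjust(table["p"].to_numpy()) if len(table) else []
        table["class"] = _classify(table["q"].to_numpy())
        return table

    # -- sklearn-style entry point ------------------------------------------
    def fit(self, m: pd.DataFrame, y=None):
        """Build the network from a batch-corrected log-TPM matrix."""
        adjacency = build_adjacency(m, power=self.power, network_type=self.network_type)
        self.modules_ = self.detect_modules(adjacency)
        self.eigengenes_ = self.module_eigengenes(m, self.modules_)
        if len(self.eigengenes_):
            self.kme_ = self.compute_kme(m, self.eigengenes_)
            self.hub_genes_, self.hub_threshold_ = self.hub_genes(self.kme_, self.modules_)
        else:
            self.kme_ = pd.DataFrame(index=m.index)
            self.hub_genes_, self.hub_threshold_ = set(), float("nan")
        self.n_modules_ = len(set(self.modules_) - {"M0"})
        return self
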