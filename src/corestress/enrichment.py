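"""One-sided Fisher overlap tests with Benjamini-Hochberg FDR.

The same machinery serves transcription-factor (family) enrichment, "classic
algorithm" term enrichment against a caller-supplied gene->term map (any
ontology propagation is the caller's responsibility), and co-expression
module overlaps. Significance classes follow the conventional FDR bands:
``enriched`` (q < 0.05), ``near`` (0.05 <= q < 0.1), ``ns`` otherwise.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ALL_TF_LABEL = "ALL_TF"


def _fisher_counts(a, b, c, d):
    """One-sided (greater) Fisher p and sample odds ratio from 2x2 counts.

    ``a`` = |set & annotated|, ``b`` = |set - annotated|,
    ``c`` = |annotated - set|, ``d`` = |neither|. The p-value is the upper
    hypergeometric tail P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c,
    n=a+b), identical to ``fisher_exact(..., alternative="greater")``.
    Accepts scalars or equal-length arrays. Odds ratio is the sample OR
    (a*d)/(b*c), with inf when the denominator is zero and the numerator is
    not, and NaN for 0/0.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("2x2 counts must be non-negative")
    total = a + b + c + d
    p = hypergeom.sf(a - 1, total, a + c, a + b)
    num = (a * d).astype(float)
    den = (b * c).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(den > 0, num / den, np.where(num > 0, np.inf, np.nan))
    if np.ndim(p) == 0:
        return float(odds), float(p)
    return odds, p


def fisher_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, float]:
    """One-sided Fisher test of overlap of two gene sets in a universe.

    Returns ``(odds_ratio, p)`` testing whether ``set_a`` contains more of
    ``set_b`` than expected under hypergeometric sampling from the
    universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    return _fisher_counts(a, b, c, d)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _classify(q: np.ndarray) -> np.ndarray:
    return np.where(q < 0.05, "enriched", np.where(q < 0.1, "near", "ns"))


def _counts_row(gene_set: set[str], annotated: set[str], universe_size: int) -> tuple[int, int, int, int]:
    a = len(gene_set & annotated)
    b = len(gene_set) - a
    c = len(annotated) - a
    d = universe_size - a - b - c
    return a, b, c, d


def _enrichment_table(
    gene_set: set[str],
    annotations: Mapping[str, set[str]],
    universe: set[str],
    label_name: str,
) -> pd.DataFrame:
    rows = []
    n = len(universe)
    for label in annotations:
        a, b, c, d = _counts_row(gene_set, annotations[label], n)
        odds, p = _fisher_counts(a, b, c, d)
        rows.append({label_name: label, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = fdr_adjust(table["p"].to_numpy())
        table["class"] = _classify(table["q"].to_numpy())
    return table


def term_enrichment(
    gene_set: set[str],
    annotations: Mapping[str, Iterable[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Per-term one-sided Fisher tests ("classic" algorithm) with FDR.

    Each term is tested independently against the universe (no ontology
    structure is used; supply pre-propagated annotations if terms form a
    DAG). Terms with an empty annotation within the universe are skipped
    with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    gene_set = set(gene_set) & universe
    clipped: dict[str, set[str]] = {}
    skipped = []
    for term, genes in annotations.items():
        genes = set(genes) & universe
        if genes:
            clipped[term] = genes
        else:
            skipped.append(term)
    if skipped:
        warnings.warn(f"terms with no annotated genes in universe skipped: {len(skipped)}", stacklevel=2)
    table = _enrichment_table(gene_set, clipped, universe, "term")
    if len(table):
        table = table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return table


def tf_family_enrichment(
    gene_sets: Mapping[str, Iterable[str]],
    tf_catalog: Mapping[str, str],
    universe: set[str],
) -> pd.DataFrame:
    """TF and TF-family enrichment for one or more gene sets.

    For each gene set (e.g. up- and down-regulated core sets, tested
    separately) every TF family in the catalog gets a one-sided Fisher test
    with FDR across families within that set. A pooled all-TFs test
    (labelled ``ALL_TF``) is run per set and corrected separately from the
    family battery. Families absent from the universe keep a row with
    a = 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    families: dict[str, set[str]] = {}
    for gene, family in tf_catalog.items():
        if gene in universe:
            families.setdefault(family, set()).add(gene)
    for family in set(tf_catalog.values()) - set(families):
        families[family] = set()
    all_tfs = set().union(*families.values()) if families else set()

    out = []
    for name in gene_sets:
        gene_set = set(gene_sets[name]) & universe
        table = _enrichment_table(gene_set, families, universe, "family")
        table.insert(0, "set", name)
        out.append(table)
        a, b, c, d = _counts_row(gene_set, all_tfs, len(universe))
        odds, p = _fisher_counts(a, b, c, d)
        pooled = pd.DataFrame(
            [
                {
                    "set": name,
                    "family": ALL_TF_LABEL,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p": p,
                    "q": p,  # single test in its own FDR battery
                    "class": _classify(np.array([p]))[0],
                }
            ]
        )
        out.append(pooled)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()
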