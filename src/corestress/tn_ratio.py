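"""TN-ratio differential expression and core / stress-specific set operations.

For one experiment (BioProject) the TN-ratio of a gene is

    TN = (mean stressed TPM + 1) / (mean control TPM + 1)

computed on raw TPM (the ratio is within-experiment, so batch effects
cancel; batch correction is reserved for the multivariate analyses). A gene
is called up-regulated when TN > 2 and down-regulated when TN < 0.5, with
strict inequalities. Per stressor, the up (down) set is the union over that
stressor's experiments; core genes are the intersection of the per-stressor
sets across all stressors, and stress-specific genes are those
differentially expressed under exactly one stressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UP_THRESHOLD_DEFAULT = 2.0
DOWN_THRESHOLD_DEFAULT = 0.5


def bioproject_stressors(meta: pd.DataFrame) -> dict[str, str]:
    """Map each BioProject to the stressor it studied.

    A BioProject is assumed to study one stressor (plus controls); a
    BioProject with several distinct stress treatments raises.
    """
    out: dict[str, str] = {}
    for bp, grp in meta.groupby("bioproject", sort=True):
        stresses = sorted(set(grp["treatment"]) - {"control"})
        if len(stresses) != 1:
            raise ValueError(
                f"BioProject {bp!r} has stress treatments {stresses}; expected exactly one"
            )
        out[str(bp)] = stresses[0]
    return out


def compute_tn_ratio(m: pd.DataFrame, meta: pd.DataFrame, bioproject: str) -> pd.Series:
    """Per-gene TN-ratio for one BioProject on raw TPM."""
    samples = meta.index[meta["bioproject"] == bioproject]
    samples = [s for s in samples if s in m.columns]
    if not samples:
        raise ValueError(f"BioProject {bioproject!r} has no samples in the matrix")
    sub_meta = meta.loc[samples]
    control = sub_meta.index[sub_meta["treatment"] == "control"]
    stressed = sub_meta.index[sub_meta["treatment"] != "control"]
    if len(control) == 0:
        raise ValueError(f"BioProject {bioproject!r} has no control samples")
    if len(stressed) == 0:
        raise ValueError(f"BioProject {bioproject!r} has no stressed samples")
    t_mean = m.loc[:, stressed].mean(axis=1)
    n_mean = m.loc[:, control].mean(axis=1)
    ratio = (t_mean + 1.0) / (n_mean + 1.0)
    ratio.name = bioproject
    return ratio


def tn_ratio_table(m: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """TN-ratios for every BioProject: genes x BioProjects."""
    bps = sorted(meta["bioproject"].unique())
    return pd.DataFrame({bp: compute_tn_ratio(m, meta, bp) for bp in bps})


@dataclass
class DECallTable:
    """Per (gene, BioProject) TN-ratios and up/down/none calls."""

    ratios: pd.DataFrame  # genes x bioprojects, positive
    calls: pd.DataFrame  # genes x bioprojects, values in {"up", "down", "none"}
    up_threshold: float = UP_THRESHOLD_DEFAULT
    down_threshold: float = DOWN_THRESHOLD_DEFAULT
    bioproject_stressor: dict[str, str] = field(default_factory=dict)


def classify_de(
    ratios: pd.DataFrame,
    up_threshold: float = UP_THRESHOLD_DEFAULT,
    down_threshold: float = DOWN_THRESHOLD_DEFAULT,
    bioproject_stressor: dict[str, str] | None = None,
) -> DECallTable:
    """Call genes up/down/none from TN-ratios with strict thresholds.

    A ratio of exactly 2 (or exactly 0.5) is *not* differentially
    expressed: the thresholds are strict inequalities.
    """
    if down_threshold >= up_threshold:
        raise ValueError(
            f"down_threshold ({down_threshold}) must be below up_threshold ({up_threshold})"
        )
    values = ratios.to_numpy(dtype=float)
    if np.any(values <= 0) or np.any(~np.isfinite(values)):
        raise ValueError("TN-ratios must be positive and finite")
    calls = np.where(values > up_threshold, "up", np.where(values < down_threshold, "down", "none"))
    return DECallTable(
        ratios=ratios,
        calls=pd.DataFrame(calls, index=ratios.index, columns=ratios.columns),
        up_threshold=up_threshold,
        down_threshold=down_threshold,
        bioproject_stressor=dict(bioproject_stressor or {}),
    )


def stressor_union(
    calls: DECallTable, meta: pd.DataFrame | None = None
) -> dict[str, dict[str, set[str]]]:
    """Union of up/down calls over each stressor's BioProjects.

    A gene is in a stressor's ``up`` set when it is called up in at least
    one of that stressor's experiments (likewise ``down``); with opposite
    calls in two experiments of one stressor it appears in both sets.
    """
    bp_stress = calls.bioproject_stressor
    if not bp_stress:
        if meta is None:
            raise ValueError("need sample metadata or a bioproject->stressor map")
        bp_stress = bioproject_stressors(meta)
    missing = set(calls.calls.columns) - set(bp_stress)
    if missing:
        raise ValueError(f"BioProjects without a stressor label: {sorted(missing)}")

    out: dict[str, dict[str, set[str]]] = {}
    for stressor in sorted(set(bp_stress.values())):
        bps = [bp for bp in calls.calls.columns if bp_stress[bp] == stressor]
        if not bps:
            raise ValueError(f"stressor {stressor!r} has no BioProjects")
        sub = calls.calls.loc[:, bps]
        up = set(sub.index[(sub == "up").any(axis=1)])
        down = set(sub.index[(sub == "down").any(axis=1)])
        out[stressor] = {"up": up, "down": down}
    return out


def core_genes_set_ops(
    per_stressor: dict[str, dict[str, set[str]]],
) -> tuple[set[str], set[str]]:
    """Core sets: genes up (down) in every stressor's union set."""
    stressors = list(per_stressor)
    if not stressors:
        raise ValueError("no stressors provided")
    core_up = set.intersection(*(per_stressor[s]["up"] for s in stressors))
    core_down = set.intersection(*(per_stressor[s]["down"] for s in stressors))
    return core_up, core_down


def stress_specific_genes(
    per_stressor: dict[str, dict[str, set[str]]],
) -> dict[str, dict[str, set[str]]]:
    """Genes differentially expressed under exactly one stressor.

    A gene is specific to stressor ``s`` iff it is in s's up or down union
    set and in no other stressor's up or down set; within ``s`` it is
    reported as up and/or down according to its calls.
    """
    de_any = {s: d["up"] | d["down"] for s, d in per_stressor.items()}
    specific: dict[str, dict[str, set[str]]] = {}
    for s in per_stressor:
        others: set[str] = set()
        for o, genes in de_any.items():
            if o != s:
                others |= genes
        only_here = de_any[s] - others
        specific[s] = {
            "up": per_stressor[s]["up"] & only_here,
            "down": per_stressor[s]["down"] & only_here,
        }
    return specific


@dataclass
class StressorGeneSets:
    """Full set-operations result: per-stressor, core, and specific sets."""

    per_stressor: dict[str, dict[str, set[str]]]
    core_up: set[str]
    core_down: set[str]
    specific: dict[str, dict[str, set[str]]]
    calls: DECallTable

    @property
    def core(self) -> set[str]:
        return self.core_up | self.core_down


def run_tn_ratio_analysis(
    m: pd.DataFrame,
    meta: pd.DataFrame,
    up_threshold: float = UP_THRESHOLD_DEFAULT,
    down_threshold: float = DOWN_THRESHOLD_DEFAULT,
) -> StressorGeneSets:
    """TN-ratio DE calls and all derived gene sets for a raw TPM compendium."""
    bp_stress = bioproject_stressors(meta)
    ratios = tn_ratio_table(m, meta)
    calls = classify_de(ratios, up_threshold, down_threshold, bp_stress)
    per_stressor = stressor_union(calls)
    core_up, core_down = core_genes_set_ops(per_stressor)
    specific = stress_specific_genes(per_stressor)
    return StressorGeneSets(
        per_stressor=per_stressor,
        core_up=core_up,
        core_down=core_down,
        specific=specific,
        calls=calls,
    )
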