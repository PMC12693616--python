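"""Synthetic multi-BioProject stress compendia with planted ground truth.

The generator emulates the structure of a public-SRA style compendium:
several independent experiments (BioProjects) per stressor, each with its
own batch effect, containing control and stress-treated samples. Genes are
planted as core stress-responsive (differentially expressed under every
stressor), stress-specific (responsive under exactly one stressor),
co-expressed blocks, and transcription-factor/target pairs, so that each
downstream stage can be scored against a known truth.

Expression is simulated on the log2 scale and back-transformed to TPM:

    log2 TPM[g, s] = mu_g + treatment effects + block/TF latents
                     + shift_b + scale_b * eps[g, s]

with ``mu_g ~ Normal(5, 2)`` (a realistic TPM dynamic range),
``shift_b ~ Normal(0, batch_shift_sd)`` an additive per-BioProject batch
location, ``scale_b = exp(Normal(0, batch_scale_sd))`` a multiplicative
per-BioProject batch scale acting on the noise (exactly the location/scale
model ComBat assumes), and log-normal biological noise whose standard
deviation on the natural-log scale is ``sqrt(ln(1 + noise_cv**2))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_STRESSORS: tuple[str, ...] = (
    "drought",
    "heat",
    "cold",
    "salt",
    "flooding",
    "low_nitrogen",
)

#: Maize TF family names used to label simulated regulators.
TF_FAMILIES: tuple[str, ...] = (
    "AP2/ERF-ERF",
    "NAC",
    "bZIP",
    "HSF",
    "C2C2-CO-like",
    "MYB",
    "WRKY",
    "Orphans",
)


@dataclass
class SimConfig:
    """Configuration of a synthetic compendium.

    Parameters
    ----------
    n_genes:
        Total number of genes.
    n_bioprojects_per_stressor:
        Independent experiments per stressor; 3 mirrors the "at least three
        independent experiments" inclusion criterion of typical compendia.
    stressors:
        Stress treatment labels; every BioProject also has controls.
    samples_per_group:
        Samples in each of the control and stressed groups of a BioProject.
    n_core_up, n_core_down:
        Planted core genes, up-/down-regulated under every stressor.
    n_specific_per_stressor:
        Planted genes responsive under exactly one stressor (half up,
        half down).
    core_fold_change, specific_fold_change:
        Multiplicative effect (>1) on the stressed-group mean TPM.
    batch_shift_sd:
        SD of the per-BioProject additive shift on the log2 scale.
    batch_scale_sd:
        SD (log scale) of the per-BioProject multiplicative noise scale.
    noise_cv:
        Biological coefficient of variation of the log-normal noise.
    n_tfs, targets_per_tf, tf_regulation_strength:
        Regulators, their target counts, and the weight with which a
        target's log profile copies its regulator's latent activity.
    tf_activity_sd:
        SD of the per-sample latent activity of each TF (drives the
        TF->target co-variation the GRN stage must recover).
    n_coexpr_blocks, block_size, block_signal_sd:
        Co-expressed gene blocks sharing a latent sample profile.
    specific_bioproject_fraction:
        Fraction of a stressor's BioProjects in which its specific genes
        are planted (>=1 BioProject always).
    n_tissues, tissue_separation:
        Optional two-tissue mode: tissue 2 samples get a global additive
        log2 offset so ordination separates tissues first.
    seed:
        Generator seed; output is bit-identical for a fixed config.
    """

    n_genes: int = 2000
    n_bioprojects_per_stressor: int = 3
    stressors: tuple[str, ...] = DEFAULT_STRESSORS
    samples_per_group: int = 6
    n_core_up: int = 60
    n_core_down: int = 40
    n_specific_per_stressor: int = 24
    core_fold_change: float = 4.0
    specific_fold_change: float = 4.0
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.1
    noise_cv: float = 0.2
    n_tfs: int = 40
    targets_per_tf: int = 10
    tf_regulation_strength: float = 0.5
    tf_activity_sd: float = 1.0
    n_coexpr_blocks: int = 4
    block_size: int = 30
    block_signal_sd: float = 1.0
    specific_bioproject_fraction: float = 1.0
    n_tissues: int = 1
    tissue_separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stressors = tuple(self.stressors)
        counts = {
            "n_genes": self.n_genes,
            "n_bioprojects_per_stressor": self.n_bioprojects_per_stressor,
            "samples_per_group": self.samples_per_group,
            "n_core_up": self.n_core_up,
            "n_core_down": self.n_core_down,
            "n_specific_per_stressor": self.n_specific_per_stressor,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.core_fold_change < 1 or self.specific_fold_change < 1:
            raise ValueError("fold changes must be >= 1 (1 = no planted effect)")
        if not 0 <= self.tf_regulation_strength <= 1:
            raise ValueError("tf_regulation_strength must be in [0, 1]")
        if not 0 < self.specific_bioproject_fraction <= 1:
            raise ValueError("specific_bioproject_fraction must be in (0, 1]")
        if self.n_tissues not in (1, 2):
            raise ValueError("n_tissues must be 1 or 2")
        planted = (
            self.n_core_up
            + self.n_core_down
            + self.n_specific_per_stressor * len(self.stressors)
            + self.n_tfs
        )
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class GroundTruth:
    """Planted gene identities of a simulated compendium."""

    core_up: set[str]
    core_down: set[str]
    specific: dict[str, set[str]]
    specific_up: dict[str, set[str]]
    specific_down: dict[str, set[str]]
    tf_catalog: dict[str, str]
    regulator_targets: dict[str, set[str]]
    coexpr_block: dict[str, str] = field(default_factory=dict)

    @property
    def core(self) -> set[str]:
        return self.core_up | self.core_down

    def to_json(self) -> str:
        payload = {
            "core_up": sorted(self.core_up),
            "core_down": sorted(self.core_down),
            "specific": {s: sorted(g) for s, g in self.specific.items()},
            "specific_up": {s: sorted(g) for s, g in self.specific_up.items()},
            "specific_down": {s: sorted(g) for s, g in self.specific_down.items()},
            "tf_catalog": self.tf_catalog,
            "regulator_targets": {t: sorted(g) for t, g in self.regulator_targets.items()},
            "coexpr_block": self.coexpr_block,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float


def score_recovery(predicted: set[str], truth: set[str], universe: set[str]) -> RecoveryMetrics:
    """Precision/recall/F1 of a predicted gene set against planted truth.

    An empty prediction with nonempty truth scores precision 0 (not NaN),
    so recovery curves degrade gracefully.
    """
    predicted, truth, universe = set(predicted), set(truth), set(universe)
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth must be subsets of the universe")
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return RecoveryMetrics(precision=precision, recall=recall, f1=f1)


def _log2_noise_sd(cv: float) -> float:
    # CV of a log-normal with natural-log sd s is sqrt(exp(s^2)-1).
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


def generate_compendium(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a TPM compendium with known planted structure.

    Returns
    -------
    expression:
        genes x samples non-negative TPM DataFrame.
    metadata:
        per-sample table indexed by sample id with columns
        ``bioproject``, ``treatment``, ``tissue``, ``genotype``.
    truth:
        :class:`GroundTruth` with every planted gene identity.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_stressors = len(cfg.stressors)

    width = max(5, len(str(cfg.n_genes)))
    genes = np.array([f"Gene{i:0{width}d}" for i in range(1, cfg.n_genes + 1)])

    # --- gene role assignment (deterministic block layout) -----------------
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        sel = genes[cursor : cursor + n]
        cursor += n
        return sel

    core_up = take(cfg.n_core_up)
    core_down = take(cfg.n_core_down)
    specific_up: dict[str, np.ndarray] = {}
    specific_down: dict[str, np.ndarray] = {}
    for s in cfg.stressors:
        n_up = (cfg.n_specific_per_stressor + 1) // 2
        specific_up[s] = take(n_up)
        specific_down[s] = take(cfg.n_specific_per_stressor - n_up)
    tfs = take(cfg.n_tfs)

    background = genes[cursor:]
    block_assign: dict[str, str] = {}
    block_members: list[np.ndarray] = []
    bg_cursor = 0
    for b in range(cfg.n_coexpr_blocks):
        members = background[bg_cursor : bg_cursor + cfg.block_size]
        if len(members) < cfg.block_size:
            raise ValueError("not enough background genes for co-expression blocks")
        bg_cursor += cfg.block_size
        block_members.append(members)
        for g in members:
            block_assign[g] = f"B{b + 1}"
    free_background = background[bg_cursor:]

    regulator_targets: dict[str, set[str]] = {}
    if cfg.n_tfs > 0 and cfg.targets_per_tf > 0:
        if len(free_background) < cfg.targets_per_tf:
            raise ValueError("not enough background genes for TF targets")
        for tf in tfs:
            picks = rng.choice(len(free_background), size=cfg.targets_per_tf, replace=False)
            regulator_targets[tf] = set(free_background[picks])

    tf_catalog = {tf: TF_FAMILIES[i % len(TF_FAMILIES)] for i, tf in enumerate(tfs)}

    # --- sample layout ------------------------------------------------------
    sample_ids: list[str] = []
    bioprojects: list[str] = []
    treatments: list[str] = []
    tissues: list[str] = []
    bp_names: list[str] = []
    bp_of_stressor: dict[str, list[str]] = {s: [] for s in cfg.stressors}
    for s in cfg.stressors:
        for j in range(1, cfg.n_bioprojects_per_stressor + 1):
            bp = f"PRJ_{s}_{j}"
            bp_names.append(bp)
            bp_of_stressor[s].append(bp)
            tissue = "leaf" if cfg.n_tissues == 1 or j % 2 == 1 else "root"
            for i in range(1, cfg.samples_per_group + 1):
                sample_ids.append(f"{bp}_control_{i}")
                bioprojects.append(bp)
                treatments.append("control")
                tissues.append(tissue)
            for i in range(1, cfg.samples_per_group + 1):
                sample_ids.append(f"{bp}_{s}_{i}")
                bioprojects.append(bp)
                treatments.append(s)
                tissues.append(tissue)

    metadata = pd.DataFrame(
        {
            "bioproject": bioprojects,
            "treatment": treatments,
            "tissue": tissues,
            "genotype": "B73",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    n_samples = len(sample_ids)
    gene_index = pd.Index(genes, name="gene_id")
    gene_pos = {g: i for i, g in enumerate(genes)}

    # --- log2-scale signal ---------------------------------------------------
    mu = rng.normal(5.0, 2.0, size=cfg.n_genes)
    log2fc_core = np.log2(cfg.core_fold_change)
    log2fc_spec = np.log2(cfg.specific_fold_change)

    signal = np.tile(mu[:, None], (1, n_samples))

    treat = metadata["treatment"].to_numpy()
    bp_arr = metadata["bioproject"].to_numpy()
    stressed_mask = treat != "control"

    idx_core_up = np.array([gene_pos[g] for g in core_up])
    idx_core_down = np.array([gene_pos[g] for g in core_down])
    signal[np.ix_(idx_core_up, np.where(stressed_mask)[0])] += log2fc_core
    signal[np.ix_(idx_core_down, np.where(stressed_mask)[0])] -= log2fc_core

    specific_planted_bps: dict[str, list[str]] = {}
    for s in cfg.stressors:
        bps = bp_of_stressor[s]
        n_planted = max(1, int(round(cfg.specific_bioproject_fraction * len(bps))))
        planted_bps = bps[:n_planted]
        specific_planted_bps[s] = planted_bps
        cols = np.where((treat == s) & np.isin(bp_arr, planted_bps))[0]
        if len(specific_up[s]):
            signal[np.ix_([gene_pos[g] for g in specific_up[s]], cols)] += log2fc_spec
        if len(specific_down[s]):
            signal[np.ix_([gene_pos[g] for g in specific_down[s]], cols)] -= log2fc_spec

    # latent TF activities; targets copy a weighted, noise-free version
    tf_activity = rng.normal(0.0, 1.0, size=(cfg.n_tfs, n_samples)) * cfg.tf_activity_sd
    for t, tf in enumerate(tfs):
        signal[gene_pos[tf], :] += tf_activity[t]
        for target in sorted(regulator_targets.get(tf, ())):
            signal[gene_pos[target], :] += cfg.tf_regulation_strength * tf_activity[t]

    block_latent = rng.normal(0.0, 1.0, size=(cfg.n_coexpr_blocks, n_samples)) * cfg.block_signal_sd
    for b, members in enumerate(block_members):
        for g in members:
            signal[gene_pos[g], :] += block_latent[b]

    if cfg.n_tissues == 2:
        root_cols = np.where(metadata["tissue"].to_numpy() == "root")[0]
        signal[:, root_cols] += cfg.tissue_separation

    # --- batch effects and noise --------------------------------------------
    shift = rng.normal(0.0, 1.0, size=len(bp_names)) * cfg.batch_shift_sd
    scale = np.exp(rng.normal(0.0, 1.0, size=len(bp_names)) * cfg.batch_scale_sd)
    bp_index = {bp: k for k, bp in enumerate(bp_names)}
    col_shift = np.array([shift[bp_index[bp]] for bp in bp_arr])
    col_scale = np.array([scale[bp_index[bp]] for bp in bp_arr])

    eps = rng.normal(0.0, 1.0, size=(cfg.n_genes, n_samples)) * _log2_noise_sd(cfg.noise_cv)
    log2_expr = signal + col_shift[None, :] + col_scale[None, :] * eps

    expression = pd.DataFrame(
        np.exp2(log2_expr), index=gene_index, columns=pd.Index(sample_ids, name="sample_id")
    )

    truth = GroundTruth(
        core_up=set(core_up),
        core_down=set(core_down),
        specific={
            s: set(specific_up[s]) | set(specific_down[s]) for s in cfg.stressors
        },
        specific_up={s: set(v) for s, v in specific_up.items()},
        specific_down={s: set(v) for s, v in specific_down.items()},
        tf_catalog=tf_catalog,
        regulator_targets=regulator_targets,
        coexpr_block=block_assign,
    )
    return expression, metadata, truth


def write_compendium(
    outdir: str | Path,
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> None:
    """Write expression/metadata TSVs plus ground-truth JSON and TF catalog."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression.to_csv(outdir / "expression.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
        catalog = pd.DataFrame(
            sorted(truth.tf_catalog.items()), columns=["gene_id", "family"]
        )
        catalog.to_csv(outdir / "tf_catalog.tsv", sep="\t", index=False)


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict (e.g. parsed YAML)."""
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation options: {sorted(unknown)}")
    if "stressors" in d:
        d = dict(d, stressors=tuple(d["stressors"]))
    return SimConfig(**d)
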