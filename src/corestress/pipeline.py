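"""End-to-end orchestration of the compendium analysis stages.

``run_pipeline`` executes the stages in dependency order —
preprocess -> TN-ratio DE -> random forest -> co-expression -> enrichment
-> GRN — from one :class:`PipelineConfig`, writing every artifact with a
JSON provenance record (stage parameters, derived seed, input hashes). The
combined core set is the union of the set-operations and random-forest core
sets, reported with per-method membership flags.

One global seed fans out to per-stage seeds (a stable hash of the stage
name and the seed) so any stage can be re-run independently and
reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from corestress import io as csio
from corestress.coexpression import CoexpressionNetwork
from corestress.enrichment import term_enrichment, tf_family_enrichment
from corestress.grn import infer_grn, mean_incoming_weight, repeated_dunnett
from corestress.preprocessing import combat_adjust, filter_zero_variance, log_transform
from corestress.rf_core import DEFAULT_SUBSET_SIZES, HoldOneStressorOutRF, annotate_direction
from corestress.tn_ratio import run_tn_ratio_analysis

logger = logging.getLogger("corestress")


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters for one pipeline run."""

    expression: str
    metadata: str
    outdir: str
    tf_catalog: str | None = None
    gmt: str | None = None
    # stage toggles
    run_de: bool = True
    run_rf: bool = True
    run_coexpression: bool = True
    run_enrichment: bool = True
    run_grn: bool = True
    # stage parameters
    up_threshold: float = 2.0
    down_threshold: float = 0.5
    rf_n_iter: int = 10
    rf_cv: int = 3
    rf_top_k: int = 6000
    rf_subset_sizes: tuple[int, ...] = DEFAULT_SUBSET_SIZES
    rf_feature_curve: bool = False
    soft_power: int = 9
    min_module_size: int = 20
    cut_height: float = 0.9
    hub_percentile: float = 0.95
    grn_n_trees: int = 100
    grn_n_reps: int = 5000
    n_jobs: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown pipeline options: {sorted(unknown)}")
        if "rf_subset_sizes" in payload:
            payload["rf_subset_sizes"] = tuple(payload["rf_subset_sizes"])
        return cls(**payload)

    def validate(self) -> None:
        for name in ("expression", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("tf_catalog", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.down_threshold >= self.up_threshold:
            raise ValueError("down_threshold must be below up_threshold")
        if not 0 < self.hub_percentile < 1:
            raise ValueError("hub_percentile must be in (0, 1)")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _provenance(outdir: Path, stage: str, params: dict, inputs: dict[str, str], seed: int) -> None:
    record = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "input_hashes": {k: _file_hash(v) for k, v in inputs.items()},
    }
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(record, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all enabled stages; returns the output directory.

    A stage failure aborts the run with an error naming the stage; outputs
    of completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"expression": config.expression, "metadata": config.metadata}

    expr = csio.read_expression(config.expression)
    meta = csio.read_metadata(config.metadata)
    missing = set(expr.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    def _stage(name, fn):
        logger.info("stage %s: starting", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: done", name)

    state: dict = {}

    def preprocess():
        logged = log_transform(expr)
        filtered = filter_zero_variance(logged)
        corrected = combat_adjust(filtered, meta.loc[filtered.columns, "bioproject"])
        csio.write_expression(corrected, outdir / "corrected.tsv")
        _provenance(outdir, "preprocess", {}, inputs, stage_seed(config.seed, "preprocess"))
        state["corrected"] = corrected

    _stage("preprocess", preprocess)
    universe = set(state["corrected"].index)

    if config.run_de:
        def de():
            sets = run_tn_ratio_analysis(expr, meta, config.up_threshold, config.down_threshold)
            state["de"] = sets
            sets.calls.ratios.to_csv(outdir / "tn_ratios.tsv", sep="\t")
            csio.write_gene_set(sets.core_up, outdir / "core_up.txt")
            csio.write_gene_set(sets.core_down, outdir / "core_down.txt")
            for s, d in sets.specific.items():
                for direction in ("up", "down"):
                    csio.write_gene_set(d[direction], outdir / f"specific_{s}_{direction}.txt")
            _provenance(
                outdir,
                "de",
                {"up_threshold": config.up_threshold, "down_threshold": config.down_threshold},
                inputs,
                stage_seed(config.seed, "de"),
            )

        _stage("de", de)

    if config.run_rf:
        def rf():
            model = HoldOneStressorOutRF(
                n_iter=config.rf_n_iter,
                cv=config.rf_cv,
                top_k=config.rf_top_k,
                subset_sizes=tuple(config.rf_subset_sizes),
                run_feature_curve=config.rf_feature_curve,
                n_jobs=config.n_jobs,
                seed=stage_seed(config.seed, "rf"),
            ).fit(state["corrected"], meta)
            state["rf"] = model
            csio.write_gene_set(model.core_genes_, outdir / "rf_core.txt")
            imp = pd.DataFrame({s: r.importances for s, r in model.results_.items()})
            imp.to_csv(outdir / "rf_importances.tsv", sep="\t")
            report = {}
            for s, r in model.results_.items():
                report[s] = {
                    "best_params": r.best_params,
                    "metrics": r.metrics,
                    "optimal_subset_size": r.optimal_subset_size,
                }
                if r.feature_curve is not None and len(r.feature_curve):
                    report[s]["feature_curve"] = {
                        str(k): {m: v for m, v in row.items()}
                        for k, row in r.feature_curve.to_dict("index").items()
                    }
            (outdir / "rf_results.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
            _provenance(
                outdir,
                "rf",
                {"n_iter": config.rf_n_iter, "cv": config.rf_cv, "top_k": config.rf_top_k},
                inputs,
                stage_seed(config.seed, "rf"),
            )

        _stage("rf", rf)

    # combined core set with per-method membership (union of methods)
    if config.run_de or config.run_rf:
        def combine():
            setops = state["de"].core if "de" in state else set()
            rf_set = state["rf"].core_genes_ if "rf" in state else set()
            combined = sorted(setops | rf_set)
            table = pd.DataFrame(
                {
                    "gene_id": combined,
                    "set_operations": [g in setops for g in combined],
                    "random_forest": [g in rf_set for g in combined],
                }
            )
            table.to_csv(outdir / "core_combined.tsv", sep="\t", index=False)
            state["combined_core"] = set(combined)
            if "de" in state:
                direction = annotate_direction(state["combined_core"], state["de"].per_stressor)
                (outdir / "core_direction.json").write_text(json.dumps(direction, indent=1) + "\n")

        _stage("combine", combine)

    if config.run_coexpression:
        def coexpress():
            net = CoexpressionNetwork(
                power=config.soft_power,
                min_module_size=config.min_module_size,
                cut_height=config.cut_height,
                hub_percentile=config.hub_percentile,
            ).fit(state["corrected"])
            state["network"] = net
            net.modules_.to_csv(outdir / "modules.tsv", sep="\t")
            net.kme_.to_csv(outdir / "kme.tsv", sep="\t")
            csio.write_gene_set(net.hub_genes_, outdir / "hubs.txt")
            if "combined_core" in state and state["combined_core"]:
                enr = net.module_set_enrichment(net.modules_, state["combined_core"])
                enr.to_csv(outdir / "module_core_enrichment.tsv", sep="\t", index=False)
            _provenance(
                outdir,
                "coexpress",
                {
                    "power": config.soft_power,
                    "min_module_size": config.min_module_size,
                    "cut_height": config.cut_height,
                    "hub_percentile": config.hub_percentile,
                },
                inputs,
                stage_seed(config.seed, "coexpress"),
            )

        _stage("coexpress", coexpress)

    if config.run_enrichment and config.tf_catalog:
        def enrich():
            catalog = csio.read_tf_catalog(config.tf_catalog)
            gene_sets: dict[str, set[str]] = {}
            if "de" in state:
                gene_sets["core_up_setops"] = state["de"].core_up
                gene_sets["core_down_setops"] = state["de"].core_down
            if "combined_core" in state:
                gene_sets["core_combined"] = state["combined_core"]
            if gene_sets:
                table = tf_family_enrichment(gene_sets, catalog, universe)
                table.to_csv(outdir / "tf_enrichment.tsv", sep="\t", index=False)
            if config.gmt and "combined_core" in state:
                annotations = csio.read_gmt(config.gmt)
                terms = term_enrichment(state["combined_core"], annotations, universe)
                terms.to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
            _provenance(outdir, "enrich", {}, inputs, stage_seed(config.seed, "enrich"))

        _stage("enrich", enrich)

    if config.run_grn and config.tf_catalog:
        def grn():
            catalog = csio.read_tf_catalog(config.tf_catalog)
            tf_list = sorted(set(catalog) & universe)
            seed = stage_seed(config.seed, "grn")
            edges = infer_grn(
                state["corrected"], tf_list, seed=seed,
                n_trees=config.grn_n_trees, n_jobs=config.n_jobs,
            )
            edges.to_csv(outdir / "grn_edges.tsv", sep="\t", index=False)
            if "de" in state:
                sets = state["de"]
                groups: dict[str, list[str]] = {"core": sorted(sets.core)}
                claimed = set(sets.core)
                for s, d in sets.specific.items():
                    members = (d["up"] | d["down"]) - set(tf_list)
                    groups[f"specific_{s}"] = sorted(members)
                    claimed |= members
                targets = set(edges["target"]) - set(tf_list)
                groups["other"] = sorted(targets - claimed)
                groups = {k: v for k, v in groups.items() if len(v) >= 2}
                if "other" in groups and len(groups) >= 2:
                    weights = mean_incoming_weight(edges, set(tf_list))
                    result = repeated_dunnett(
                        weights, groups, control="other",
                        n_reps=config.grn_n_reps, seed=seed,
                    )
                    result.table.to_json(outdir / "grn_dunnett.json", orient="records", indent=1)
                else:
                    warnings.warn("too few usable gene groups for Dunnett comparison", stacklevel=2)
            _provenance(
                outdir,
                "grn",
                {"n_trees": config.grn_n_trees, "n_reps": config.grn_n_reps},
                inputs,
                seed,
            )

        _stage("grn", grn)

    run_record = {"config": asdict(config)}
    run_record["config"]["rf_subset_sizes"] = list(config.rf_subset_sizes)
    (outdir / "run.json").write_text(json.dumps(run_record, indent=1, sort_keys=True) + "\n")
    return outdir
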