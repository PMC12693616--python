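"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices are TSV with gene ids in the first column and a header
row of sample ids; metadata is TSV indexed by sample id; gene sets are one
id per line; annotations use GMT (term, description, genes...); the TF
catalog is a two-column TSV (gene_id, family).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

REQUIRED_META_COLUMNS = ("bioproject", "treatment")


def read_expression(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index.name = "gene_id"
    if m.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if m.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    return m


def write_expression(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    meta.index.name = "sample_id"
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


def read_gene_set(path: str | Path) -> set[str]:
    lines = Path(path).read_text().splitlines()
    return {line.strip() for line in lines if line.strip()}


def write_gene_set(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_tf_catalog(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "family"} <= set(df.columns):
        raise ValueError("TF catalog needs columns gene_id and family")
    return dict(zip(df["gene_id"], df["family"]))


def write_tf_catalog(catalog: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(catalog.items()), columns=["gene_id", "family"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    annotations: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs term, description and >=1 gene: {line[:60]!r}")
        term, _desc, *genes = parts
        annotations[term] = {g for g in genes if g}
    return annotations


def write_gmt(annotations: dict[str, set[str]], path: str | Path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations):
            genes = "\t".join(sorted(annotations[term]))
            fh.write(f"{term}\t{description}\t{genes}\n")


def read_ground_truth(path: str | Path):
    from corestress.simulate import GroundTruth

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        core_up=set(payload["core_up"]),
        core_down=set(payload["core_down"]),
        specific={s: set(g) for s, g in payload["specific"].items()},
        specific_up={s: set(g) for s, g in payload.get("specific_up", {}).items()},
        specific_down={s: set(g) for s, g in payload.get("specific_down", {}).items()},
        tf_catalog=dict(payload["tf_catalog"]),
        regulator_targets={t: set(g) for t, g in payload["regulator_targets"].items()},
        coexpr_block=dict(payload.get("coexpr_block", {})),
    )
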