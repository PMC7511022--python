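"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV, UTF-8, '.' decimal; a missing intensity is an *empty*
cell, never zero.  Peptide matrices carry the proteotypic mapping in their
first two columns (peptide_id, protein_id); sample columns are keyed
``<subject>_<day>_<measurement>``.  Annotations are a GAF-style 3-column
subset (term_id, protein_id, namespace).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .matrix import PeptideMatrix, ProteinMatrix


def write_behavior_tsv(behavior: pd.DataFrame, path) -> None:
    behavior.to_csv(path, sep="\t", index=False, na_rep="")


def read_behavior_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    for col in ("m11", "m12", "m21", "m22"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_peptide_tsv(m: PeptideMatrix, path) -> None:
    out = m.intensities.copy()
    out.insert(0, "protein_id", m.mapping.reindex(out.index))
    out.index.name = "peptide_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_peptide_tsv(path, provenance: str = "qvalue") -> PeptideMatrix:
    df = pd.read_csv(path, sep="\t", index_col="peptide_id")
    mapping = df.pop("protein_id")
    return PeptideMatrix(intensities=df, mapping=mapping, provenance=provenance)


def write_protein_tsv(m: ProteinMatrix, path) -> None:
    out = m.intensities.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_protein_tsv(path, **flags) -> ProteinMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    return ProteinMatrix(intensities=df, **flags)


def write_mapping_tsv(mapping: pd.Series, path) -> None:
    mapping.rename("protein_id").rename_axis("peptide_id").to_csv(path, sep="\t")


def read_mapping_tsv(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="peptide_id")["protein_id"]


def write_annotation_tsv(terms: dict[str, set[str]], path,
                         namespace: str = "biological_process") -> None:
    rows = [
        {"term_id": term, "protein_id": pid, "namespace": namespace}
        for term in sorted(terms)
        for pid in sorted(terms[term])
    ]
    pd.DataFrame(rows, columns=["term_id", "protein_id", "namespace"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation_tsv(path, namespace: str | None = "biological_process"
                        ) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    if namespace is not None and "namespace" in df.columns:
        df = df[df["namespace"] == namespace]
    return {t: set(g["protein_id"]) for t, g in df.groupby("term_id")}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
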