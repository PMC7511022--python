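"""Peptide and protein intensity matrices: filtering, aggregation, fill-in,
median normalization, and within-day fold changes.

Two extraction variants of the same label-free DIA experiment feed this
module: a strict per-observation confidence filter ("qvalue", more missing
cells) and a sparse setting that keeps any analyte passing confidence at
least once ("qvalue_sparse", few missing cells).  The peptide-level dataset
(used for the ANCOVA) keeps peptides with ≤10% missing values; the
protein-level dataset sums proteotypic peptides per protein, fills missing
cells from the sparse variant, and drops proteins with >5% missing.  Both
are normalized per sample to median 1 and natural-log transformed; fold
changes are log2(measurement 2 / measurement 1) per subject and day on the
normalized (un-logged) scale.

Missing cells are NaN in memory and empty strings in TSV — never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


def sample_key(subject: str, day: int, measurement: int) -> str:
    return f"{subject}_{day}_{measurement}"


def parse_sample_key(key: str) -> tuple[str, int, int]:
    subject, day, meas = key.rsplit("_", 2)
    return subject, int(day), int(meas)


@dataclass
class PeptideMatrix:
    """Peptide × sample intensities with a proteotypic peptide→protein map."""

    intensities: pd.DataFrame  # index peptide_id, columns sample keys
    mapping: pd.Series  # peptide_id -> protein_id
    provenance: str = "qvalue"  # qvalue | qvalue_sparse

    def __post_init__(self) -> None:
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicate sample columns")
        if (self.intensities.fillna(0) < 0).any().any():
            raise ValueError("negative intensities")

    @property
    def proteins(self) -> pd.Index:
        return pd.Index(sorted(self.mapping.unique()))


@dataclass
class ProteinMatrix:
    """Protein × sample intensities with normalization/log state flags."""

    intensities: pd.DataFrame  # index protein_id
    normalized: bool = False
    logged: bool = False


@dataclass
class FoldChangeTable:
    """log2(measurement 2 / measurement 1) per (subject, day).

    ``values`` has the feature IDs as index and a (subject, day) MultiIndex on
    the columns; ``mapping`` is carried along for peptide-level tables.
    """

    values: pd.DataFrame
    mapping: pd.Series | None = None

    def day(self, day: int) -> pd.DataFrame:
        """Feature × subject slice for one day."""
        sub = self.values.loc[:, self.values.columns.get_level_values("day") == day]
        sub = sub.copy()
        sub.columns = sub.columns.get_level_values("subject")
        return sub


def filter_peptides(m: PeptideMatrix, max_missing: float = 0.10) -> PeptideMatrix:
    """Drop peptides whose missing fraction exceeds ``max_missing`` (strict >).

    Row order is preserved; exactly 10% missing is kept.
    """
    if m.intensities.empty:
        raise ValueError("empty peptide matrix")
    frac = m.intensities.isna().mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} peptides exceed {max_missing:.0%} missing; none kept"
        )
    return replace(
        m,
        intensities=m.intensities.loc[keep],
        mapping=m.mapping.loc[keep[keep].index],
    )


def aggregate_to_proteins(m: PeptideMatrix) -> ProteinMatrix:
    """Sum proteotypic peptide intensities per protein.

    A cell is the sum over the protein's *observed* peptides and is missing
    only when every constituent peptide is missing in that sample.
    """
    extra = m.intensities.index.difference(m.mapping.index)
    if len(extra):
        raise ValueError(f"peptides without protein mapping: {list(extra[:5])}")
    groups = m.mapping.reindex(m.intensities.index)
    summed = m.intensities.groupby(groups).sum(min_count=1)
    summed.index.name = "protein_id"
    return ProteinMatrix(intensities=summed)


def fill_and_filter(
    qv: ProteinMatrix, qvs: ProteinMatrix, max_missing: float = 0.05
) -> ProteinMatrix:
    """Fill missing qvalue cells from the sparse variant, then drop rows >5% missing.

    Both matrices must share the same row/column universe.  A cell missing in
    both stays missing and counts toward the threshold; the boundary is
    strict (exactly 5% missing is kept).
    """
    if not qv.intensities.index.equals(qvs.intensities.index) or not qv.intensities.columns.equals(
        qvs.intensities.columns
    ):
        raise ValueError("qvalue and qvalue-sparse matrices differ in rows/columns")
    filled = qv.intensities.where(~qv.intensities.isna(), qvs.intensities)
    frac = filled.isna().mean(axis=1)
    keep = frac <= max_missing
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} proteins exceed {max_missing:.0%} missing after fill"
        )
    return ProteinMatrix(intensities=filled.loc[keep])


def normalize_and_log(m):
    """Scale each sample to median 1 (over non-missing cells), then natural log.

    Accepts a :class:`ProteinMatrix` or :class:`PeptideMatrix`; returns the
    same type with state flags set (for protein matrices).  Normalizing an
    already-normalized matrix is a no-op in value terms (medians are 1).
    """
    df = m.intensities
    medians = df.median(axis=0, skipna=True)
    if (medians <= 0).any() or medians.isna().any():
        bad = medians.index[(medians <= 0) | medians.isna()]
        raise ValueError(f"non-positive or undefined column median: {list(bad[:5])}")
    normalized = df / medians
    logged = np.log(normalized)
    if isinstance(m, ProteinMatrix):
        return ProteinMatrix(intensities=logged, normalized=True, logged=True)
    out = replace(m, intensities=logged)
    return out


def normalized_scale(m) -> pd.DataFrame:
    """Median-1 normalized intensities *without* the log (for fold changes)."""
    df = m.intensities
    medians = df.median(axis=0, skipna=True)
    if (medians <= 0).any() or medians.isna().any():
        raise ValueError("non-positive or undefined column median")
    return df / medians


def fold_changes(intensities: pd.DataFrame, mapping: pd.Series | None = None) -> FoldChangeTable:
    """log2 fold change of measurement 2 over measurement 1 per (subject, day).

    ``intensities`` must be on the un-logged normalized scale with sample-key
    columns; a fold change is missing whenever either measurement is missing.
    """
    parsed = [parse_sample_key(c) for c in intensities.columns]
    cols = pd.DataFrame(parsed, columns=["subject", "day", "meas"])
    out = {}
    for (subject, day), grp in cols.groupby(["subject", "day"], sort=True):
        meas = grp.set_index("meas").index
        if 1 not in meas or 2 not in meas:
            continue
        i1 = intensities.iloc[:, grp.index[grp["meas"] == 1][0]]
        i2 = intensities.iloc[:, grp.index[grp["meas"] == 2][0]]
        out[(subject, day)] = np.log2(i2 / i1)
    values = pd.DataFrame(out)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["subject", "day"])
    return FoldChangeTable(values=values, mapping=mapping)


def drop_samples(m: PeptideMatrix, excluded: list[str]) -> PeptideMatrix:
    """Explicit sample exclusion (e.g. haemolytic samples), by sample key."""
    missing = [s for s in excluded if s not in m.intensities.columns]
    if missing:
        raise ValueError(f"excluded samples not in matrix: {missing}")
    return replace(m, intensities=m.intensities.drop(columns=list(excluded)))
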