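"""Placebo-regulated protein discovery by peptide-level ANCOVA.

For each protein, all Day-2 peptide log2 fold changes (measurement 2 vs 1)
are stacked as observations — peptides act as replicate measurements of
their protein, which multiplies the effective sample size for proteins with
many peptides — and modeled with between-subject factors group and sex plus
the subject's Day-1 fold change of the same peptide as covariate, adjusting
for individual baseline reactivity.  The group main-effect p-value (Type II)
decides significance; the adjusted placebo−control difference gives the
regulation direction.

Treating peptides as independent replicates is a deliberate power device,
not a variance-correct model: observations from one subject share the
subject's biology.  A per-subject-averaged sensitivity mode (one observation
per subject, peptide fold changes averaged within protein) is available and
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linmod import type2_anova
from .matrix import FoldChangeTable

ANCOVA_TERMS = [("grp",), ("sex",), ("fc1",)]
ANCOVA_TERMS_INTERACTION = [("grp",), ("sex",), ("grp", "sex"), ("fc1",)]


@dataclass
class AncovaResult:
    protein_id: str
    n_peptides: int
    n_obs: int
    p_group: float
    p_sex: float
    group_diff: float  # adjusted placebo − control difference (log2 units)
    skipped_reason: str | None = None


def peptide_ancova(
    fc: FoldChangeTable,
    arm: pd.Series,
    sex: pd.Series,
    per_subject_average: bool = False,
    include_interaction: bool = False,
) -> pd.DataFrame:
    """Per-protein ANCOVA of Day-2 peptide fold changes.

    ``fc`` is a peptide-level fold-change table carrying the peptide→protein
    mapping; ``arm``/``sex`` are indexed by subject.  Returns a DataFrame with
    one row per protein (protein_id, n_peptides, n_obs, p_group, p_sex,
    direction, fdr_group); proteins that cannot be fit (single arm
    represented, no residual df) appear with NaN p and a ``skipped`` reason.
    The FDR column is informational — selection uses the uncorrected p.
    """
    if fc.mapping is None:
        raise ValueError("peptide-level fold-change table requires a mapping")
    fc2 = fc.day(2)
    fc1 = fc.day(1)
    subjects = fc2.columns
    arm_v = arm.reindex(subjects)
    sex_v = sex.reindex(subjects)
    grp_code = np.where(arm_v.to_numpy() == "placebo", 0.5, -0.5)
    sex_code = np.where(sex_v.to_numpy() == "f", 0.5, -0.5)
    terms = ANCOVA_TERMS_INTERACTION if include_interaction else ANCOVA_TERMS

    rows = []
    for protein, pep_index in fc.mapping.groupby(fc.mapping).groups.items():
        pep_index = fc2.index.intersection(pep_index)
        if len(pep_index) == 0:
            continue
        y2 = fc2.loc[pep_index].to_numpy(dtype=float)
        y1 = fc1.reindex(index=pep_index, columns=subjects).to_numpy(dtype=float)
        G = np.broadcast_to(grp_code, y2.shape)
        S = np.broadcast_to(sex_code, y2.shape)
        if per_subject_average:
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
                y2 = np.nanmean(y2, axis=0, keepdims=True)
                y1 = np.nanmean(y1, axis=0, keepdims=True)
            G, S = grp_code[None, :], sex_code[None, :]
        ok = np.isfinite(y2) & np.isfinite(y1)
        y, x1 = y2[ok], y1[ok]
        g, s = G[ok], S[ok]
        row = {
            "protein_id": protein,
            "n_peptides": int(len(pep_index)),
            "n_obs": int(ok.sum()),
        }
        n_arms = len(np.unique(g))
        if n_arms < 2 or ok.sum() < len(terms) + 2:
            row.update(p_group=np.nan, p_sex=np.nan, group_diff=np.nan,
                       skipped="single arm" if n_arms < 2 else "too few observations")
            rows.append(row)
            continue
        data = {"grp": g, "sex": s, "fc1": x1}
        tab = type2_anova(terms, data, y)
        # adjusted group difference: coefficient of the ±0.5 grp code in the
        # full model equals the covariate-adjusted placebo − control contrast
        from .linmod import design_matrix, ols
        beta = ols(design_matrix(terms, data), y).beta
        row.update(
            p_group=tab[("grp",)]["p"],
            p_sex=tab[("sex",)]["p"],
            group_diff=float(beta[1]),
            skipped=None,
        )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("protein_id").sort_index()
    fitted = out["p_group"].notna()
    out["fdr_group"] = np.nan
    if fitted.any():
        from statsmodels.stats.multitest import multipletests
        out.loc[fitted, "fdr_group"] = multipletests(
            out.loc[fitted, "p_group"], method="fdr_bh"
        )[1]
    out["direction"] = np.where(out["group_diff"] > 0, "+", "-")
    out.loc[~fitted, "direction"] = ""
    return out


def select_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Proteins with group p ≤ alpha, partitioned by adjusted-difference sign.

    Returns the significant subset with its ``direction`` column ("+": more
    abundant after placebo, "−": less).  No multiplicity correction is
    applied at this step; the ``fdr_group`` column travels along.
    """
    if results.empty:
        raise ValueError("empty ANCOVA results")
    sig = results[results["p_group"].notna() & (results["p_group"] <= alpha)]
    return sig.sort_values("p_group")
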