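"""Per-protein dissection of Day-2 fold-change variance by experimental factors.

Each protein's Day-2 fold change across subjects is modeled as

    y = μ + β1·DAS + β2·grp + β3·sex + β4·DAS·grp + β5·DAS·sex
          + β6·grp·sex + β7·DAS·grp·sex

with the day-adjusted score (nausea, MS or NTT) continuous and group/sex as
centered two-level factors.  Remaining missing cells are completed by
predictive-mean-matching multiple imputation (m datasets); a Tukey-bisquare
robust pre-pass flags and removes outlying subjects before the final OLS fit.
The model R² is the regression sum of squares over the total sum of squares;
per-term shares are Type II partial sums of squares rescaled to add up to the
model R².  Per-imputation results are summarized by element-wise medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linmod import Term, bisquare_keep_mask, design_matrix, ols, type2_anova

VARIANCE_TERMS: list[Term] = [
    ("das",), ("grp",), ("sex",),
    ("das", "grp"), ("das", "sex"), ("grp", "sex"),
    ("das", "grp", "sex"),
]

TERM_LABELS = {
    ("das",): "DAS", ("grp",): "grp", ("sex",): "sex",
    ("das", "grp"): "DASxgrp", ("das", "sex"): "DASxsex",
    ("grp", "sex"): "grpxsex", ("das", "grp", "sex"): "3way",
}

PMM_DONORS = 5
MIN_SUBJECTS = 12


def _covariate_frame(das, arm, sex) -> pd.DataFrame:
    return pd.DataFrame({
        "das": np.asarray(das, dtype=float),
        "grp": np.where(np.asarray(arm) == "placebo", 0.5, -0.5),
        "sex": np.where(np.asarray(sex) == "f", 0.5, -0.5),
    })


def impute_missing(
    fc: pd.DataFrame,
    das: pd.Series,
    arm: pd.Series,
    sex: pd.Series,
    m: int = 5,
    k: int = PMM_DONORS,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Predictive-mean-matching imputation of a protein × subject table.

    For each protein row, observed cells are regressed on (DAS, group, sex);
    every missing cell is filled with the *observed* value of a donor drawn
    uniformly from the ``k`` observed cells with the nearest predicted mean.
    Returns ``m`` independently completed copies.  Rows with fewer than ``k``
    donors fall back to the single nearest donor (with a warning).
    """
    subjects = fc.columns
    cov = _covariate_frame(das.reindex(subjects), arm.reindex(subjects),
                           sex.reindex(subjects))
    X = design_matrix([("das",), ("grp",), ("sex",)],
                      {c: cov[c].to_numpy() for c in cov})
    rng = np.random.default_rng(seed)
    completions = [fc.copy() for _ in range(m)]
    values = fc.to_numpy(dtype=float)
    for i in range(values.shape[0]):
        y = values[i]
        miss = ~np.isfinite(y)
        if not miss.any():
            continue
        obs = ~miss
        if obs.sum() <= X.shape[1]:
            raise ValueError(
                f"row {fc.index[i]}: too few observed cells ({obs.sum()}) to impute"
            )
        beta = ols(X[obs], y[obs]).beta
        pred = X @ beta
        donors_pred = pred[obs]
        donors_y = y[obs]
        kk = k
        if len(donors_y) < k:
            warnings.warn(
                f"row {fc.index[i]}: only {len(donors_y)} donors (<{k}); "
                "falling back to nearest single donor"
            )
            kk = 1
        for j in np.where(miss)[0]:
            order = np.argsort(np.abs(donors_pred - pred[j]), kind="stable")[:kk]
            for completed in completions:
                completed.iloc[i, j] = donors_y[rng.choice(order)]
    return completions


@dataclass
class VarianceComposition:
    protein_id: str
    fractions: dict[str, float]  # term label -> explained-variance share
    r2: float
    p_values: dict[str, float]
    n_outliers_removed: int
    n_imputations: int = 1


def fit_variance_model(
    y: np.ndarray, das: np.ndarray, arm: np.ndarray, sex: np.ndarray,
    protein_id: str = "",
) -> VarianceComposition:
    """Fit the 7-term model to one protein (one completed dataset).

    A bisquare robust pre-pass flags outliers (converged weight < 0.01); the
    final fit is plain OLS on the retained subjects.  Per-term shares are
    Type II partial SS rescaled so the seven terms sum to the model R².
    """
    cov = _covariate_frame(das, arm, sex)
    y = np.asarray(y, dtype=float)
    data = {c: cov[c].to_numpy() for c in cov}
    X = design_matrix(VARIANCE_TERMS, data)
    keep = bisquare_keep_mask(X, y)
    if keep.sum() < MIN_SUBJECTS:
        raise ValueError(
            f"{protein_id or 'protein'}: only {int(keep.sum())} subjects left "
            f"after outlier removal (< {MIN_SUBJECTS})"
        )
    data_k = {c: v[keep] for c, v in data.items()}
    yk = y[keep]
    if np.linalg.matrix_rank(design_matrix(VARIANCE_TERMS, data_k)) < len(VARIANCE_TERMS) + 1:
        raise ValueError(f"{protein_id or 'protein'}: design rank-deficient after outlier removal")
    tab = type2_anova(VARIANCE_TERMS, data_k, yk)
    ss_terms = {TERM_LABELS[t]: tab[t]["ss"] for t in VARIANCE_TERMS}
    fit = ols(design_matrix(VARIANCE_TERMS, data_k), yk)
    r2 = fit.r2
    total_ss = sum(ss_terms.values())
    if total_ss > 0:
        fractions = {lbl: ss / total_ss * r2 for lbl, ss in ss_terms.items()}
    else:
        fractions = {lbl: 0.0 for lbl in ss_terms}
    return VarianceComposition(
        protein_id=protein_id,
        fractions=fractions,
        r2=float(r2),
        p_values={TERM_LABELS[t]: tab[t]["p"] for t in VARIANCE_TERMS},
        n_outliers_removed=int((~keep).sum()),
    )


def summarize_imputations(per_imputation: list[VarianceComposition]) -> VarianceComposition:
    """Element-wise median across imputations (fractions, R², p-values)."""
    if not per_imputation:
        raise ValueError("no compositions to summarize")
    labels = per_imputation[0].fractions.keys()
    return VarianceComposition(
        protein_id=per_imputation[0].protein_id,
        fractions={l: float(np.median([c.fractions[l] for c in per_imputation]))
                   for l in labels},
        r2=float(np.median([c.r2 for c in per_imputation])),
        p_values={l: float(np.median([c.p_values[l] for c in per_imputation]))
                  for l in labels},
        n_outliers_removed=int(np.median(
            [c.n_outliers_removed for c in per_imputation])),
        n_imputations=len(per_imputation),
    )


def dissect_variance(
    fc_day2: pd.DataFrame,
    das: pd.Series,
    arm: pd.Series,
    sex: pd.Series,
    m: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full variance dissection: impute, fit per protein, pool by medians.

    ``fc_day2`` is protein × subject.  Subjects with a missing DAS are
    dropped first (the score, not the proteome, defines the model).  Returns
    one row per protein: frac_* columns, R2, n_outliers, p_* columns.
    """
    subjects = fc_day2.columns
    das_v = das.reindex(subjects)
    ok = das_v.notna()
    fc_day2 = fc_day2.loc[:, ok]
    subjects = fc_day2.columns
    das_v = das_v[ok]
    arm_v, sex_v = arm.reindex(subjects), sex.reindex(subjects)

    completions = impute_missing(fc_day2, das_v, arm_v, sex_v, m=m, seed=seed)
    rows = []
    for pid in fc_day2.index:
        per_imp = [
            fit_variance_model(
                comp.loc[pid].to_numpy(), das_v.to_numpy(),
                arm_v.to_numpy(), sex_v.to_numpy(), protein_id=pid,
            )
            for comp in completions
        ]
        pooled = summarize_imputations(per_imp)
        row = {"protein_id": pid, "R2": pooled.r2,
               "n_outliers": pooled.n_outliers_removed}
        row.update({f"frac_{l}": v for l, v in pooled.fractions.items()})
        row.update({f"p_{l}": v for l, v in pooled.p_values.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein_id")


def significant_factor_proteins(
    compositions: pd.DataFrame, alpha: float = 0.05
) -> dict[str, list[str]]:
    """Proteins with at least one term p ≤ alpha, mapped to those terms.

    Feeds the per-factor GO enrichment: the returned dict maps protein_id to
    the list of significant term labels (e.g. ``["grp", "DASxgrp"]``).
    """
    p_cols = [c for c in compositions.columns if c.startswith("p_")]
    out: dict[str, list[str]] = {}
    for pid, row in compositions[p_cols].iterrows():
        hits = [c[2:] for c in p_cols if row[c] <= alpha]
        if hits:
            out[pid] = hits
    return out
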