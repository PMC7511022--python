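"""Behavioral statistics: day-adjusted scores, ANOVAs, responders, χ² tests.

The trial measures each subject twice per day (measurement 1 at baseline,
measurement 2 after the nauseating vection stimulus) on two days; treatment
(placebo vs no treatment) happens only on Day 2.  The day-adjusted score

    DAS = (m22 − m21) − (m12 − m11)

is the Day-2 stimulus-induced change corrected for the Day-1 change, so a
negative DAS for nausea means the Day-2 rise was smaller than the Day-1 rise.
DAS values are compared between arms and sexes by two-way fixed-effects
ANOVA, with a boxplot-convention (Tukey fences) outlier re-fit reported
alongside.  A placebo *responder* shows at least a 50% reduction of the
vection-induced symptom rise from Day 1 to Day 2; responder proportions are
compared by Pearson χ² without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MEASURES = ("nausea", "ms", "ntt")

#: required columns of a behavioral table (long by measure)
BEHAVIOR_COLUMNS = ["subject", "arm", "sex", "measure", "m11", "m12", "m21", "m22"]


def day_adjusted_score(m11, m12, m21, m22):
    """DAS = (m22 − m21) − (m12 − m11); any missing input yields NaN.

    Accepts scalars or aligned arrays.
    """
    m11, m12, m21, m22 = (np.asarray(m, dtype=float) for m in (m11, m12, m21, m22))
    return (m22 - m21) - (m12 - m11)


def das_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-subject DAS for every measure, wide format.

    ``behavior`` is long by measure with columns :data:`BEHAVIOR_COLUMNS`.
    Returns one row per subject with columns ``das_<measure>`` plus
    ``tukey_outlier_<measure>`` flags (fences at 1.5×IQR per arm).
    """
    missing = set(BEHAVIOR_COLUMNS) - set(behavior.columns)
    if missing:
        raise ValueError(f"behavioral table lacks columns: {sorted(missing)}")
    das = behavior.assign(
        das=day_adjusted_score(
            behavior["m11"], behavior["m12"], behavior["m21"], behavior["m22"]
        )
    )
    wide = (
        das.set_index(["subject", "arm", "sex", "measure"])["das"]
        .unstack("measure")
        .rename(columns=lambda m: f"das_{m}")
        .reset_index()
    )
    for measure in das["measure"].unique():
        col = f"das_{measure}"
        flags = pd.Series(False, index=wide.index)
        for _, idx in wide.groupby("arm").groups.items():
            vals = wide.loc[idx, col]
            flags.loc[idx] = tukey_outliers(vals)
        wide[f"tukey_outlier_{measure}"] = flags
    return wide


def tukey_outliers(values: pd.Series, k: float = 1.5) -> pd.Series:
    """Boxplot-convention outlier flags: outside [Q1 − k·IQR, Q3 + k·IQR]."""
    v = pd.to_numeric(values, errors="coerce")
    q1, q3 = v.quantile(0.25), v.quantile(0.75)
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


@dataclass
class AnovaTable:
    """Two-way ANOVA (group, sex, interaction) with an outlier-removed re-fit."""

    table: pd.DataFrame  # index: C(arm), C(sex), C(arm):C(sex), Residual
    n: int
    table_no_outliers: pd.DataFrame | None
    n_outliers_removed: int

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "PR(>F)"])


def das_anova(
    das: pd.Series, arm: pd.Series, sex: pd.Series, remove_outliers: bool = True
) -> AnovaTable:
    """Two-way fixed-effects ANOVA of DAS on group and sex (Type II SS).

    Rows with missing DAS are dropped.  When ``remove_outliers`` the model is
    re-fit after removing Tukey-fence outliers (computed per arm) and the
    second table is reported alongside, mirroring the boxplot-based outlier
    handling of the behavioral analysis.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"das": pd.to_numeric(das, errors="coerce"),
                       "arm": np.asarray(arm), "sex": np.asarray(sex)}).dropna()
    counts = df.groupby(["arm", "sex"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError(f"need ≥2 subjects per arm×sex cell, got:\n{counts}")
    if df["das"].nunique() == 1:
        raise ValueError("DAS constant across subjects: F undefined")

    def _fit(d: pd.DataFrame) -> pd.DataFrame:
        model = smf.ols("das ~ C(arm) * C(sex)", data=d).fit()
        return anova_lm(model, typ=2)

    table = _fit(df)
    table_clean, n_removed = None, 0
    if remove_outliers:
        keep = pd.Series(True, index=df.index)
        for _, idx in df.groupby("arm").groups.items():
            keep.loc[idx] = ~tukey_outliers(df.loc[idx, "das"])
        n_removed = int((~keep).sum())
        if n_removed and keep.sum() >= 8:
            table_clean = _fit(df[keep])
    return AnovaTable(
        table=table, n=len(df), table_no_outliers=table_clean,
        n_outliers_removed=n_removed,
    )


def classify_responders(m11, m12, m21, m22, threshold: float = 0.5):
    """Responder flag: Day-2 rise at most ``(1 − threshold)`` of the Day-1 rise.

    Operates on the within-day vection-induced rises (m12 − m11 on Day 1,
    m22 − m21 on Day 2); the boundary is inclusive (exactly 50% reduction is a
    responder).  A subject with a non-positive Day-1 rise has no defined
    reduction and returns NaN (excluded from counts).  Accepts scalars or
    aligned arrays; returns float array with values 1.0, 0.0, NaN.
    """
    m11, m12, m21, m22 = (np.asarray(m, dtype=float) for m in (m11, m12, m21, m22))
    rise1 = m12 - m11
    rise2 = m22 - m21
    out = np.where(rise2 <= (1.0 - threshold) * rise1, 1.0, 0.0)
    out = np.where((rise1 > 0) & np.isfinite(rise1) & np.isfinite(rise2), out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def responder_counts(behavior: pd.DataFrame, measure: str,
                     threshold: float = 0.5) -> pd.DataFrame:
    """2×2 responder table (arm × responder) plus undefined-exclusion counts."""
    sub = behavior[behavior["measure"] == measure]
    flag = classify_responders(sub["m11"], sub["m12"], sub["m21"], sub["m22"],
                               threshold)
    res = pd.DataFrame({"arm": sub["arm"].to_numpy(), "responder": flag})
    res = res.dropna()
    table = (
        res.assign(responder=res["responder"].astype(bool))
        .groupby(["arm", "responder"]).size().unstack(fill_value=0)
        .reindex(columns=[True, False], fill_value=0)
    )
    table.attrs["n_excluded"] = int(len(sub) - len(res))
    return table


def responder_chisq(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson χ² (df=1, no continuity correction) on the 2×2 table [[a,b],[c,d]].

    Returns ``(chi2, p)``.  Margins must all be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
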