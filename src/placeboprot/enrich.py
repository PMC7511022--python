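"""GO over-representation, redundancy removal, Jaccard clustering, and
GO-signature regression prediction of day-adjusted scores.

Enrichment of a study protein set (e.g. the placebo-regulated proteins) is
tested per term with the hypergeometric upper tail P(X ≥ k) against the
detected-proteome background, followed by Benjamini–Hochberg FDR across the
tested terms.  Terms annotating *identical* protein sets (restricted to the
background) are fully redundant and collapse to one representative (the
lexicographically first term id).  Significant terms are grouped into
functional clusters: terms are nodes, an edge joins two terms whose protein
sets have Jaccard index J > 0.4, clusters are the connected components.

For each enriched term, a linear regression of the behavioral day-adjusted
score on the Day-2 fold changes of the term's significantly regulated
proteins — fitted separately in the placebo and control arms with bisquare
outlier removal — quantifies how well the term's signature tracks the
behavioral placebo response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import bisquare_keep_mask, ols


def enrich(study: set[str], annotation: dict[str, set[str]],
           background: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``study`` in every term.

    Term protein sets are intersected with ``background`` first; the study
    set must be contained in the background.  Fully redundant terms (equal
    restricted sets) are collapsed to their lexicographically first id, with
    the members recorded in ``collapsed_terms``.  Returns one row per kept
    term: k (study hits), K (term size), n (study size), N (background
    size), p, fdr — sorted by p.
    """
    stray = study - background
    if stray:
        raise ValueError(f"study proteins outside background: {sorted(stray)[:5]}")
    N, n = len(background), len(study)
    restricted: dict[str, frozenset] = {}
    for term, members in annotation.items():
        r = frozenset(members & background)
        if r:
            restricted[term] = r
    by_set: dict[frozenset, list[str]] = {}
    for term in sorted(restricted):
        by_set.setdefault(restricted[term], []).append(term)

    rows = []
    for members, terms in by_set.items():
        K = len(members)
        k = len(study & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": terms[0],
            "collapsed_terms": ",".join(terms[1:]),
            "k": k, "K": K, "n": n, "N": N, "p": p,
        })
    out = pd.DataFrame(rows).set_index("term_id")
    if len(out):
        from statsmodels.stats.multitest import multipletests
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="stable")
    return out


def jaccard_index(a: set[str], b: set[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def jaccard_cluster(term_sets: dict[str, set[str]],
                    threshold: float = 0.4) -> pd.Series:
    """Connected-component clusters of terms by Jaccard similarity.

    Edge between terms i, j iff J_ij > ``threshold`` (strict).  Returns a
    Series term_id → cluster id (0-based, ordered by first term id in the
    cluster); invariant to input order.
    """
    terms = sorted(term_sets)
    parent = {t: t for t in terms}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, ti in enumerate(terms):
        for tj in terms[i + 1:]:
            if jaccard_index(term_sets[ti], term_sets[tj]) > threshold:
                ri, rj = find(ti), find(tj)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots: dict[str, int] = {}
    labels = {}
    for t in terms:
        r = find(t)
        if r not in roots:
            roots[r] = len(roots)
        labels[t] = roots[r]
    return pd.Series(labels, name="cluster")


@dataclass
class TermDasFit:
    term_id: str
    arm: str
    n_proteins: int
    n_subjects: int
    r2: float
    p_model: float
    n_outliers_removed: int


def go_term_predict_das(
    das: pd.Series,
    fc_day2: pd.DataFrame,
    term_proteins: dict[str, set[str]],
    arm: pd.Series,
    significant_proteins: set[str] | None = None,
) -> pd.DataFrame:
    """Per-term, per-arm linear prediction of the DAS from protein fold changes.

    For every term, predictors are the term's proteins intersected with
    ``significant_proteins`` (when given) and with the rows of ``fc_day2``
    (protein × subject, Day 2).  Each arm is fit separately: bisquare outlier
    removal, then OLS of DAS on the protein fold changes; the model F-test
    p-value is FDR-corrected across terms within each arm.  Terms with fewer
    than 2 predictors, or more predictors than arm subjects, are skipped
    with a reason column.
    """
    from statsmodels.stats.multitest import multipletests

    subjects = fc_day2.columns
    das_v = das.reindex(subjects)
    arm_v = arm.reindex(subjects)
    rows = []
    for term in sorted(term_proteins):
        prots = term_proteins[term] & set(fc_day2.index)
        if significant_proteins is not None:
            prots = prots & significant_proteins
        prots = sorted(prots)
        for arm_name in ("placebo", "control"):
            in_arm = (arm_v == arm_name).to_numpy()
            row = {"term_id": term, "arm": arm_name, "n_proteins": len(prots)}
            if len(prots) < 2:
                row.update(n_subjects=0, r2=np.nan, p_model=np.nan,
                           n_outliers=0, skipped="fewer than 2 predictor proteins")
                rows.append(row)
                continue
            Xp = fc_day2.loc[prots, in_arm].to_numpy(dtype=float).T
            y = das_v[in_arm].to_numpy(dtype=float)
            ok = np.isfinite(y) & np.all(np.isfinite(Xp), axis=1)
            Xp, y = Xp[ok], y[ok]
            if len(y) <= len(prots) + 1:
                row.update(n_subjects=int(len(y)), r2=np.nan, p_model=np.nan,
                           n_outliers=0,
                           skipped="term too large: more predictors than arm subjects")
                rows.append(row)
                continue
            X = np.column_stack([np.ones(len(y)), Xp])
            keep = bisquare_keep_mask(X, y)
            if keep.sum() <= X.shape[1]:
                keep = np.ones(len(y), dtype=bool)
            fit = ols(X[keep], y[keep])
            df_model = X.shape[1] - 1
            df_resid = fit.df_resid
            if fit.tss > 0 and df_resid > 0 and fit.rss > 0:
                F = (fit.tss - fit.rss) / df_model / (fit.rss / df_resid)
                p_model = float(stats.f.sf(F, df_model, df_resid))
            else:
                p_model = np.nan
            row.update(n_subjects=int(keep.sum()), r2=float(fit.r2),
                       p_model=p_model, n_outliers=int((~keep).sum()),
                       skipped=None)
            rows.append(row)
    columns = ["term_id", "arm", "n_proteins", "n_subjects", "r2", "p_model",
               "n_outliers", "skipped"]
    out = pd.DataFrame(rows, columns=columns)
    out["fdr_model"] = np.nan
    for arm_name in ("placebo", "control"):
        mask = (out["arm"] == arm_name) & out["p_model"].notna()
        if mask.any():
            out.loc[mask, "fdr_model"] = multipletests(
                out.loc[mask, "p_model"], method="fdr_bh"
            )[1]
    return out.set_index(["term_id", "arm"])
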