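"""Prediction of placebo responders from Day-2 baseline protein levels.

Placebo-arm subjects with complete protein data are labeled responder /
non-responder from their behavioral symptom reduction.  Feature selection is
two-stage: one-way ANOVA F ranks the baseline (Day-2 measurement-1) protein
log-intensities and keeps the top 5; greedy sequential forward selection
then adds proteins from the complement while each addition improves the
cross-validated misclassification rate of a linear SVM by more than a
tolerance.  The resulting "ANOVA plus" model is evaluated by stratified
k-fold cross-validation (k = 10) repeated over 10 independent fold
permutations: held-out decision values are pooled into one ROC per
permutation, the median ROC (vertical median on a fixed FPR grid) and the
mean ± SD AUC are reported, plus a pooled confusion matrix at decision
threshold 0.  A "RANDOM" null model repeats the evaluation with uniformly
drawn protein sets of the same size.

Selection honesty: by default preselection and sequential selection are
re-run inside every training split, so the reported AUC is not biased by
information from the held-out fold.  ``full_data_selection=True`` reproduces the
literal sequence — select once on the full data, then cross-validate — and
is optimistic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SVM_C = 1.0
FPR_GRID = np.linspace(0.0, 1.0, 101)


def _svm() -> SVC:
    return SVC(kernel="linear", C=SVM_C)


def anova_preselect(X: pd.DataFrame, labels: np.ndarray, k: int = 5) -> list[str]:
    """Top-``k`` proteins by one-way ANOVA F between responder classes.

    ``X`` is subjects × proteins.  Ties broken by protein id (stable sort on
    descending F).  Raises when only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both responder classes required for ANOVA preselection")
    from sklearn.feature_selection import f_classif

    F, _ = f_classif(X.to_numpy(dtype=float), labels)
    F = np.nan_to_num(F, nan=0.0)
    order = sorted(range(X.shape[1]), key=lambda j: (-F[j], X.columns[j]))
    return [X.columns[j] for j in order[: min(k, X.shape[1])]]


def _bounded(seed: int) -> int:
    return int(seed) % (2**31 - 1)


def _cv_misclassification(X: np.ndarray, y: np.ndarray, folds: int,
                          rng_seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=_bounded(rng_seed))
    errors = []
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        clf = _svm().fit(scaler.transform(X[train]), y[train])
        pred = clf.predict(scaler.transform(X[test]))
        errors.append(np.mean(pred != y[test]))
    return float(np.mean(errors))


def sequential_select(
    X: pd.DataFrame,
    labels: np.ndarray,
    base: list[str],
    tolerance: float = 0.02,
    max_additions: int = 5,
    inner_folds: int = 5,
    candidate_pool: int = 30,
    seed: int = 0,
) -> list[str]:
    """Greedy forward selection of proteins beyond the ANOVA ``base`` set.

    Candidates come from the complement of ``base``; at each round the
    candidate whose addition most reduces the cross-validated
    misclassification of the linear SVM is added, provided the improvement
    exceeds ``tolerance``; otherwise selection stops.  For tractability the
    complement is restricted to the ``candidate_pool`` best remaining
    proteins by ANOVA F (set ``candidate_pool=None`` for the full search).
    Returns only the added proteins (may be empty).
    """
    labels = np.asarray(labels, dtype=bool)
    remaining = [c for c in X.columns if c not in base]
    if candidate_pool is not None and len(remaining) > candidate_pool:
        from sklearn.feature_selection import f_classif

        F, _ = f_classif(X[remaining].to_numpy(dtype=float), labels)
        F = np.nan_to_num(F, nan=0.0)
        order = sorted(range(len(remaining)), key=lambda j: (-F[j], remaining[j]))
        remaining = [remaining[j] for j in order[:candidate_pool]]

    selected = list(base)
    added: list[str] = []
    if not np.isfinite(tolerance):
        return added
    best_err = _cv_misclassification(
        X[selected].to_numpy(dtype=float), labels, inner_folds, seed
    )
    for _ in range(max_additions):
        scores = []
        for cand in remaining:
            err = _cv_misclassification(
                X[selected + [cand]].to_numpy(dtype=float), labels,
                inner_folds, seed,
            )
            scores.append((err, cand))
        if not scores:
            break
        err, cand = min(scores)
        if best_err - err > tolerance:
            selected.append(cand)
            added.append(cand)
            remaining.remove(cand)
            best_err = err
        else:
            break
    return added


@dataclass
class ClassifierReport:
    selected: list[str]
    auc_mean: float
    auc_sd: float
    aucs: list[float]
    median_roc: pd.DataFrame  # columns fpr, tpr
    confusion: dict[str, int]  # TN, FN, FP, TP pooled over permutations
    random_auc_mean: float
    random_auc_sd: float
    random_aucs: list[float]
    n_subjects: int
    mode: str  # "honest" | "full-data"


def _one_permutation_roc(
    X: np.ndarray, y: np.ndarray, feature_idx_per_fold, folds: int, seed: int
):
    """Pooled held-out decision values for one fold permutation.

    ``feature_idx_per_fold`` is a callable (train_idx → column indices) so
    honest mode can re-select features per training split.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=_bounded(seed))
    dec = np.empty(len(y))
    for train, test in skf.split(X, y):
        cols = feature_idx_per_fold(train)
        scaler = StandardScaler().fit(X[np.ix_(train, cols)])
        clf = _svm().fit(scaler.transform(X[np.ix_(train, cols)]), y[train])
        dec[test] = clf.decision_function(scaler.transform(X[np.ix_(test, cols)]))
    return dec


def evaluate_models(
    X: pd.DataFrame,
    labels: np.ndarray,
    k_folds: int = 10,
    permutations: int = 10,
    n_random: int | None = None,
    seed: int = 0,
    full_data_selection: bool = False,
    n_preselect: int = 5,
    sfs_kwargs: dict | None = None,
) -> ClassifierReport:
    """Cross-validated evaluation of the ANOVA-plus and RANDOM models.

    Per permutation the stratified fold assignment is re-drawn, the linear
    SVM is trained on z-scored training folds, and held-out decision values
    are pooled into one ROC.  ``n_random`` RANDOM repetitions (default:
    ``permutations``) draw uniform protein sets of the same size as the
    selected set.  The selected set reported is always the full-data
    selection (it is what a study would publish); in honest mode the AUC
    comes from fold-internal re-selection.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) < k_folds:
        raise ValueError(f"{len(labels)} subjects < {k_folds} folds")
    class_counts = [int((~labels).sum()), int(labels.sum())]
    if min(class_counts) < k_folds:
        k_folds = max(2, min(class_counts))
    if n_random is None:
        n_random = permutations
    sfs_kwargs = dict(sfs_kwargs or {})
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    y = labels.astype(int)
    col_index = {c: j for j, c in enumerate(X.columns)}

    base = anova_preselect(X, labels, k=n_preselect)
    added = sequential_select(X, labels, base, seed=seed, **sfs_kwargs)
    selected = base + added
    selected_idx = np.array([col_index[c] for c in selected])

    def full_data_features(train):
        return selected_idx

    def honest_features(train):
        Xt = X.iloc[train]
        yt = labels[train]
        b = anova_preselect(Xt, yt, k=n_preselect)
        a = sequential_select(Xt, yt, b, seed=seed, **sfs_kwargs)
        return np.array([col_index[c] for c in b + a])

    feature_fn = full_data_features if full_data_selection else honest_features

    aucs, tprs, confusion = [], [], np.zeros(4, dtype=int)
    for p in range(permutations):
        dec = _one_permutation_roc(Xv, y, feature_fn, k_folds, seed * 1009 + p)
        fpr, tpr, _ = roc_curve(y, dec)
        aucs.append(auc(fpr, tpr))
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        pred = dec > 0
        confusion += np.array([
            int(np.sum(~pred & (y == 0))), int(np.sum(~pred & (y == 1))),
            int(np.sum(pred & (y == 0))), int(np.sum(pred & (y == 1))),
        ])

    random_aucs = []
    for r in range(n_random):
        cols = rng.choice(Xv.shape[1], size=len(selected), replace=False)
        dec = _one_permutation_roc(Xv, y, lambda train, c=cols: c, k_folds,
                                   seed * 2003 + r)
        fpr, tpr, _ = roc_curve(y, dec)
        random_aucs.append(auc(fpr, tpr))

    median_roc = pd.DataFrame({
        "fpr": FPR_GRID, "tpr": np.median(np.vstack(tprs), axis=0)
    })
    return ClassifierReport(
        selected=selected,
        auc_mean=float(np.mean(aucs)), auc_sd=float(np.std(aucs)),
        aucs=[float(a) for a in aucs],
        median_roc=median_roc,
        confusion={"TN": int(confusion[0]), "FN": int(confusion[1]),
                   "FP": int(confusion[2]), "TP": int(confusion[3])},
        random_auc_mean=float(np.mean(random_aucs)),
        random_auc_sd=float(np.std(random_aucs)),
        random_aucs=[float(a) for a in random_aucs],
        n_subjects=len(labels),
        mode="full-data" if full_data_selection else "honest",
    )


def feature_table(
    protein_log: pd.DataFrame,
    behavior: pd.DataFrame,
    arm: pd.Series,
    measure: str = "nausea",
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Baseline feature table and responder labels for the placebo arm.

    ``protein_log`` is protein × sample (logged intensities); the Day-2
    measurement-1 columns of placebo-arm subjects are extracted, subjects
    with any missing protein value are dropped (only complete proteomes are
    classified), and labels come from the behavioral responder rule for
    ``measure``.  Subjects with an undefined responder status are excluded.
    """
    from .behavior import classify_responders
    from .matrix import sample_key

    placebo_subjects = [s for s in arm.index if arm[s] == "placebo"]
    cols, subjects = [], []
    for s in placebo_subjects:
        key = sample_key(s, 2, 1)
        if key in protein_log.columns:
            cols.append(key)
            subjects.append(s)
    Xt = protein_log[cols].T
    Xt.index = subjects
    complete = Xt.notna().all(axis=1)
    Xt = Xt.loc[complete]

    beh = behavior[behavior["measure"] == measure].set_index("subject")
    beh = beh.reindex(Xt.index)
    flags = classify_responders(beh["m11"], beh["m12"], beh["m21"], beh["m22"],
                                threshold)
    defined = np.isfinite(flags)
    Xt = Xt.loc[defined]
    labels = flags[defined].astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("responder labels are single-class in the feature table")
    return Xt, labels
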