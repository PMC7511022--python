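"""End-to-end orchestration: one config, seeded stages, logged provenance.

Stage order: (optional) synthesis → sample exclusion → matrix construction
(peptide and protein datasets) → behavioral statistics (DAS, ANOVAs,
responders, χ²) → peptide-level ANCOVA → GO enrichment + clustering +
GO-signature DAS regressions → variance dissection per DAS kind →
responder prediction.  Every intermediate table is written as TSV under the
output directory and a run manifest records the seed, package versions and
the row counts at every filter, so a later stage re-run on unchanged inputs
reproduces its outputs byte-identically.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .ancova import peptide_ancova, select_significant
from .behavior import das_anova, das_table, responder_chisq, responder_counts
from .config import RunConfig
from .enrich import enrich, go_term_predict_das, jaccard_cluster
from .matrix import (
    aggregate_to_proteins,
    drop_samples,
    fill_and_filter,
    filter_peptides,
    fold_changes,
    normalize_and_log,
    normalized_scale,
)
from .responder import evaluate_models, feature_table
from .synth import simulate_cohort, write_fixtures
from .vardissect import dissect_variance, significant_factor_proteins

log = logging.getLogger("placeboprot.pipeline")


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "counts": {}, "stages": [], "versions": {}}
    import placeboprot

    for mod in ("numpy", "scipy", "pandas", "statsmodels", "sklearn"):
        manifest["versions"][mod] = __import__(mod).__version__
    manifest["versions"]["placeboprot"] = placeboprot.__version__

    # ---- inputs ------------------------------------------------------------
    t0 = _stage("inputs")
    if cfg.simulate is not None:
        sim = cfg.simulate
        study = simulate_cohort(sim)
        behavior = study.behavior
        pep_qv, pep_qvs = study.peptides_qvalue, study.peptides_qvalue_sparse
        annotation = study.annotation
        write_fixtures(study, out / "fixtures")
        arm = study.design.subjects["arm"]
        sex = study.design.subjects["sex"]
    else:
        behavior = pio.read_behavior_tsv(cfg.behavioral_path)
        pep_qv = pio.read_peptide_tsv(cfg.peptides_qvalue_path, "qvalue")
        pep_qvs = pio.read_peptide_tsv(cfg.peptides_qvalue_sparse_path,
                                       "qvalue_sparse")
        annotation = pio.read_annotation_tsv(cfg.annotation_path)
        per_subject = behavior.drop_duplicates("subject").set_index("subject")
        arm, sex = per_subject["arm"], per_subject["sex"]
    if cfg.excluded_samples:
        pep_qv = drop_samples(pep_qv, cfg.excluded_samples)
        pep_qvs = drop_samples(pep_qvs, cfg.excluded_samples)
    manifest["counts"]["peptides_input"] = int(len(pep_qv.intensities))
    manifest["counts"]["samples_input"] = int(pep_qv.intensities.shape[1])
    manifest["stages"].append(("inputs", time.perf_counter() - t0))

    # ---- matrix construction ----------------------------------------------
    t0 = _stage("matrices")
    pep_sparse_filtered = filter_peptides(pep_qvs, cfg.peptide_max_missing)
    manifest["counts"]["peptides_after_10pct_filter"] = int(
        len(pep_sparse_filtered.intensities))
    pep_fc = fold_changes(normalized_scale(pep_sparse_filtered),
                          mapping=pep_sparse_filtered.mapping)

    prot_qv = aggregate_to_proteins(pep_qv)
    prot_qvs = aggregate_to_proteins(pep_qvs)
    prot = fill_and_filter(prot_qv, prot_qvs, cfg.protein_max_missing)
    manifest["counts"]["proteins_input"] = int(len(prot_qv.intensities))
    manifest["counts"]["proteins_after_5pct_filter"] = int(len(prot.intensities))
    prot_log = normalize_and_log(prot)
    prot_fc = fold_changes(normalized_scale(prot))
    pio.write_protein_tsv(prot_log, out / "protein_log_intensities.tsv")
    prot_fc.values.to_csv(out / "protein_fold_changes.tsv", sep="\t", na_rep="")
    manifest["stages"].append(("matrices", time.perf_counter() - t0))

    # ---- behavioral statistics --------------------------------------------
    t0 = _stage("behavior")
    das = das_table(behavior)
    das.to_csv(out / "das.tsv", sep="\t", index=False, na_rep="")
    behavior_stats: dict = {}
    for measure in ("nausea", "ms", "ntt"):
        col = f"das_{measure}"
        if col not in das.columns:
            continue
        a = das_anova(das[col], das["arm"], das["sex"])
        behavior_stats[measure] = {
            "F_group": a.f("C(arm)"), "p_group": a.p("C(arm)"),
            "F_sex": a.f("C(sex)"), "p_sex": a.p("C(sex)"),
            "F_interaction": a.f("C(arm):C(sex)"),
            "p_interaction": a.p("C(arm):C(sex)"),
            "n": a.n, "n_outliers_removed": a.n_outliers_removed,
        }
    chisq = {}
    for measure in ("nausea", "ms"):
        tab = responder_counts(behavior, measure, cfg.responder_threshold)
        a, b = int(tab.loc["placebo", True]), int(tab.loc["placebo", False])
        c, d = int(tab.loc["control", True]), int(tab.loc["control", False])
        chi2, p = responder_chisq(a, b, c, d)
        chisq[measure] = {"table": [a, b, c, d], "chi2": chi2, "p": p,
                          "n_excluded": tab.attrs["n_excluded"]}
    pio.write_json({"anova": behavior_stats, "responder_chisq": chisq},
                   out / "behavior_stats.json")
    manifest["stages"].append(("behavior", time.perf_counter() - t0))

    # ---- peptide-level ANCOVA ----------------------------------------------
    t0 = _stage("ancova")
    anc = peptide_ancova(pep_fc, arm, sex)
    anc.to_csv(out / "ancova.tsv", sep="\t", na_rep="")
    sig = select_significant(anc, cfg.alpha)
    sig.to_csv(out / "ancova_significant.tsv", sep="\t", na_rep="")
    manifest["counts"]["ancova_proteins_tested"] = int(anc["p_group"].notna().sum())
    manifest["counts"]["ancova_significant"] = int(len(sig))
    manifest["counts"]["ancova_up"] = int((sig["direction"] == "+").sum())
    manifest["counts"]["ancova_down"] = int((sig["direction"] == "-").sum())
    manifest["stages"].append(("ancova", time.perf_counter() - t0))

    # ---- GO enrichment and DAS prediction ----------------------------------
    t0 = _stage("enrichment")
    background = set(prot.intensities.index)
    study_set = set(sig.index) & background
    enr = enrich(study_set, annotation, background) if study_set else pd.DataFrame()
    if len(enr):
        sig_terms = enr[enr["fdr"] <= cfg.alpha]
        term_sets = {t: annotation[t] & background for t in sig_terms.index}
        clusters = jaccard_cluster(term_sets, cfg.jaccard_threshold)
        enr = enr.join(clusters)
        enr.to_csv(out / "enrichment.tsv", sep="\t", na_rep="")
        manifest["counts"]["enriched_terms"] = int(len(sig_terms))
        manifest["counts"]["term_clusters"] = int(clusters.nunique()) if len(clusters) else 0
        das_by_subject = das.set_index("subject")
        fits = []
        for measure in ("nausea", "ms", "ntt"):
            fit = go_term_predict_das(
                das_by_subject[f"das_{measure}"], prot_fc.day(2),
                {t: annotation[t] for t in sig_terms.index}, arm,
                significant_proteins=study_set,
            )
            fit = fit.assign(measure=measure)
            fits.append(fit)
        pd.concat(fits).to_csv(out / "go_das_models.tsv", sep="\t", na_rep="")
    manifest["stages"].append(("enrichment", time.perf_counter() - t0))

    # ---- variance dissection ------------------------------------------------
    t0 = _stage("variance")
    das_by_subject = das.set_index("subject")
    for measure in ("nausea", "ms", "ntt"):
        comp = dissect_variance(
            prot_fc.day(2), das_by_subject[f"das_{measure}"], arm, sex,
            m=cfg.n_imputations, seed=cfg.seed,
        )
        comp.to_csv(out / f"variance_{measure}.tsv", sep="\t", na_rep="")
        sig_map = significant_factor_proteins(comp, cfg.alpha)
        manifest["counts"][f"variance_significant_{measure}"] = len(sig_map)
    manifest["stages"].append(("variance", time.perf_counter() - t0))

    # ---- responder prediction ----------------------------------------------
    t0 = _stage("responder_prediction")
    reports = {}
    for measure in ("nausea", "ms"):
        X, labels = feature_table(prot_log.intensities, behavior, arm, measure,
                                  cfg.responder_threshold)
        rep = evaluate_models(X, labels, k_folds=cfg.svm_folds,
                              permutations=cfg.svm_permutations, seed=cfg.seed)
        reports[measure] = {
            "selected": rep.selected, "auc_mean": rep.auc_mean,
            "auc_sd": rep.auc_sd, "random_auc_mean": rep.random_auc_mean,
            "random_auc_sd": rep.random_auc_sd, "confusion": rep.confusion,
            "n_subjects": rep.n_subjects, "mode": rep.mode,
        }
        rep.median_roc.to_csv(out / f"roc_{measure}.tsv", sep="\t", index=False)
    pio.write_json(reports, out / "responder_prediction.json")
    manifest["stages"].append(("responder_prediction", time.perf_counter() - t0))

    manifest["stages"] = [(n, round(t, 3)) for n, t in manifest["stages"]]
    pio.write_json(manifest, out / "manifest.json")
    return manifest


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO if verbose else
                        logging.WARNING, format="%(asctime)s %(name)s %(message)s")
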