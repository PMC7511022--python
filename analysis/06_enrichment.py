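#!/usr/bin/env python
"""GO enrichment of the placebo-regulated proteins and DAS prediction.

Hypergeometric over-representation against the detected-proteome background,
FDR correction, redundancy collapse, Jaccard clustering of the significant
terms, and per-term linear models predicting each day-adjusted score from
the term's significantly regulated protein fold changes in each arm.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from placeboprot import io as pio
from placeboprot import matrix as mx
from placeboprot.behavior import das_table
from placeboprot.enrich import enrich, go_term_predict_das, jaccard_cluster

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixtures = OUT / "fixtures"
    annotation = pio.read_annotation_tsv(fixtures / "annotation.tsv")
    behavior = pio.read_behavior_tsv(fixtures / "behavior.tsv")
    per_subject = behavior.drop_duplicates("subject").set_index("subject")
    sig = pd.read_csv(OUT / "ancova_significant.tsv", sep="\t",
                      index_col="protein_id")
    qv = pio.read_peptide_tsv(fixtures / "peptides_qvalue.tsv", "qvalue")
    qvs = pio.read_peptide_tsv(fixtures / "peptides_qvalue_sparse.tsv",
                               "qvalue_sparse")
    prot = mx.fill_and_filter(mx.aggregate_to_proteins(qv),
                              mx.aggregate_to_proteins(qvs), 0.05)

    background = set(prot.intensities.index)
    study_set = set(sig.index) & background
    enr = enrich(study_set, annotation, background)
    sig_terms = enr[enr["fdr"] <= 0.05]
    clusters = jaccard_cluster(
        {t: annotation[t] & background for t in sig_terms.index}, 0.4)
    enr = enr.join(clusters)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", na_rep="")
    n_clusters = clusters.nunique() if len(clusters) else 0
    print(f"enrichment: {len(enr)} non-redundant terms tested against "
          f"{len(background)} background proteins; {len(sig_terms)} "
          f"FDR-significant, grouped into {n_clusters} functional clusters")

    truth = pio.read_json(fixtures / "truth.json")
    hit = set(truth["enriched_terms"]) & set(sig_terms.index)
    print(f"planted-truth recovery: {len(hit)}/"
          f"{len(truth['enriched_terms'])} planted terms FDR-significant")

    das = das_table(behavior).set_index("subject")
    fc2 = mx.fold_changes(mx.normalized_scale(prot)).day(2)
    fits = []
    for measure in ("nausea", "ms", "ntt"):
        fit = go_term_predict_das(das[f"das_{measure}"], fc2,
                                  {t: annotation[t] for t in sig_terms.index},
                                  per_subject["arm"],
                                  significant_proteins=study_set)
        fits.append(fit.assign(measure=measure))
    all_fits = pd.concat(fits)
    all_fits.to_csv(OUT / "go_das_models.tsv", sep="\t", na_rep="")
    fitted = all_fits["fdr_model"].dropna()
    print(f"GO-signature DAS models: {len(fitted)} fitted, "
          f"{(fitted <= 0.05).sum()} FDR-significant")


if __name__ == "__main__":
    main()
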