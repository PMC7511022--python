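#!/usr/bin/env python
"""Construct the peptide and protein datasets from the intensity fixtures.

Peptide dataset (for the ANCOVA): qvalue-sparse matrix, peptides with >10%
missing removed, per-sample median normalization, log2 fold changes.
Protein dataset: proteotypic peptides summed per protein, qvalue matrix
filled from the sparse variant, proteins with >5% missing deleted, median
normalization, natural log, fold changes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from placeboprot import io as pio
from placeboprot import matrix as mx

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixtures = OUT / "fixtures"
    qv = pio.read_peptide_tsv(fixtures / "peptides_qvalue.tsv", "qvalue")
    qvs = pio.read_peptide_tsv(fixtures / "peptides_qvalue_sparse.tsv",
                               "qvalue_sparse")

    pep = mx.filter_peptides(qvs, 0.10)
    print(f"peptide dataset: {len(qvs.intensities)} → {len(pep.intensities)} "
          f"peptides after the 10% missingness filter")
    pep_fc = mx.fold_changes(mx.normalized_scale(pep), mapping=pep.mapping)
    pep_fc.values.to_csv(OUT / "peptide_fold_changes.tsv", sep="\t", na_rep="")

    prot_qv = mx.aggregate_to_proteins(qv)
    prot_qvs = mx.aggregate_to_proteins(qvs)
    prot = mx.fill_and_filter(prot_qv, prot_qvs, 0.05)
    print(f"protein dataset: {len(prot_qv.intensities)} → "
          f"{len(prot.intensities)} proteins after fill-in and the 5% filter")
    pio.write_protein_tsv(mx.normalize_and_log(prot),
                          OUT / "protein_log_intensities.tsv")
    prot_fc = mx.fold_changes(mx.normalized_scale(prot))
    prot_fc.values.to_csv(OUT / "protein_fold_changes.tsv", sep="\t", na_rep="")
    print("wrote peptide_fold_changes.tsv, protein_log_intensities.tsv, "
          "protein_fold_changes.tsv")


if __name__ == "__main__":
    main()
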