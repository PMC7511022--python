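#!/usr/bin/env python
"""Generate the synthetic study that all downstream analyses consume.

Emulates the trial design: 90 subjects (60 placebo / 30 no-treatment, both
arms half female), 2 days × 2 measurements, placebo effects on the Day-2
nausea and motion-sickness rises (and on gastric activity in females only),
a 200-protein plasma proteome with proteotypic peptides, MNAR missingness in
two extraction variants, 10 planted placebo-regulated proteins, 10 planted
responder-predictive baseline proteins, and a 30-term annotation with 3
planted enriched terms.  Fixtures are written under results/fixtures/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from placeboprot.config import SimConfig
from placeboprot.synth import simulate_cohort, write_fixtures

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240915


def main() -> None:
    cfg = SimConfig(seed=SEED)
    study = simulate_cohort(cfg)
    manifest = write_fixtures(study, OUT / "fixtures")

    n_pep, n_samp = study.peptides_qvalue.intensities.shape
    print(f"study: {len(study.design.subjects)} subjects, "
          f"{cfg.n_proteins} proteins, {n_pep} peptides, {n_samp} samples")
    print(f"missing cells (qvalue): "
          f"{study.truth['masked_fraction_qvalue']:.3f}; "
          f"(qvalue sparse): "
          f"{study.truth['masked_fraction_qvalue_sparse']:.3f}")
    print(f"planted: {len(study.truth['regulated_proteins'])} regulated, "
          f"{len(study.truth['responder_proteins'])} responder-predictive, "
          f"{len(study.truth['enriched_terms'])} enriched terms")
    print("fixtures:", ", ".join(manifest))


if __name__ == "__main__":
    main()
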