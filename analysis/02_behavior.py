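#!/usr/bin/env python
"""Behavioral statistics: day-adjusted scores, ANOVAs, responder χ².

Reads the behavioral fixture, computes DAS per subject and measure, runs the
group×sex ANOVAs (with the Tukey-fence outlier re-fit), classifies placebo
responders (≥50% reduction of the vection-induced rise), and tests the
responder proportions between arms with Pearson χ².
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from placeboprot import io as pio
from placeboprot.behavior import (
    das_anova,
    das_table,
    responder_chisq,
    responder_counts,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    behavior = pio.read_behavior_tsv(OUT / "fixtures" / "behavior.tsv")
    das = das_table(behavior)
    das.to_csv(OUT / "das.tsv", sep="\t", index=False, na_rep="")

    for measure in ("nausea", "ms", "ntt"):
        a = das_anova(das[f"das_{measure}"], das["arm"], das["sex"])
        print(f"DAS-{measure}: F_group(1,{a.n - 4}) = {a.f('C(arm)'):.2f}, "
              f"p = {a.p('C(arm)'):.2g}; "
              f"F_int = {a.f('C(arm):C(sex)'):.2f} "
              f"(p = {a.p('C(arm):C(sex)'):.2g}); "
              f"{a.n_outliers_removed} outliers flagged")

    for measure in ("nausea", "ms"):
        tab = responder_counts(behavior, measure)
        a, b = int(tab.loc["placebo", True]), int(tab.loc["placebo", False])
        c, d = int(tab.loc["control", True]), int(tab.loc["control", False])
        chi2, p = responder_chisq(a, b, c, d)
        print(f"{measure} responders: placebo {a}/{a + b}, control {c}/{c + d} "
              f"(excluded {tab.attrs['n_excluded']}); "
              f"chi2 = {chi2:.2f}, p = {p:.2g}")


if __name__ == "__main__":
    main()
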