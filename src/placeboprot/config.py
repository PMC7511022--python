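"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    The defaults emulate the trial design this pipeline targets: 90 subjects
    (60 placebo / 30 no-treatment control, each arm half female), two days
    with a baseline and a post-vection measurement per day, placebo effects
    on the Day-2 nausea and motion-sickness rises and — in females only — on
    the gastric normo-to-tachy ratio, log-normal peptide intensities with
    proteotypic peptide→protein structure, marked sex effects on protein
    abundance, intensity-dependent (MNAR) missingness, and planted
    placebo-regulated and responder-predictive proteins.
    """

    n_placebo: int = 60
    n_control: int = 30
    sex_ratio: float = 0.5  # fraction female within each arm

    # behavioral effects (standard-deviation units of the day-to-day noise)
    placebo_effect_nausea: float = 1.3
    placebo_effect_ms: float = 0.85
    placebo_effect_ntt_female: float = 0.65
    nausea_day_sd: float = 2.5
    ms_day_sd: float = 2.5
    ntt_day_sd: float = 0.5

    # proteome structure
    n_proteins: int = 200
    peptides_per_protein_mean: float = 4.5  # geometric, clipped to [1, 40]
    peptides_per_protein_max: int = 40
    frac_placebo_regulated_proteins: float = 0.05
    placebo_log2_fold_change: float = 1.0  # 2-fold on planted proteins
    frac_responder_predictive_proteins: float = 0.05
    responder_shift_sd: float = 1.0  # baseline log-intensity shift
    frac_sex_affected_proteins: float = 0.30
    sex_effect_sd: float = 1.0  # log-intensity units
    subject_sd: float = 0.3
    noise_sd: float = 0.25
    peptide_offset_sd: float = 1.0
    protein_mean_log: float = 14.0
    protein_sd_log: float = 1.5

    # missingness
    mnar_steepness: float = 1.5
    missing_target_rate: float = 0.04
    sparse_unmask_fraction: float = 0.8  # qvalue_sparse recovers this share

    # annotation
    n_terms: int = 30
    term_size_min: int = 5
    term_size_max: int = 25
    n_enriched_terms: int = 3
    enriched_term_regulated_fraction: float = 0.6

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_placebo": self.n_placebo, "n_control": self.n_control,
            "n_proteins": self.n_proteins, "n_terms": self.n_terms,
            "term_size_min": self.term_size_min, "term_size_max": self.term_size_max,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        fracs = {
            "sex_ratio": self.sex_ratio,
            "frac_placebo_regulated_proteins": self.frac_placebo_regulated_proteins,
            "frac_responder_predictive_proteins": self.frac_responder_predictive_proteins,
            "frac_sex_affected_proteins": self.frac_sex_affected_proteins,
            "sparse_unmask_fraction": self.sparse_unmask_fraction,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.missing_target_rate < 0.5:
            raise ValueError(
                "missing_target_rate must lie in [0, 0.5): higher rates would "
                "empty the matrix after the missingness filters"
            )
        if self.term_size_max < self.term_size_min:
            raise ValueError("term_size_max < term_size_min")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``simulate`` is set (synthetic study) or the three input paths
    point at existing files.  Thresholds default to the analysis constants:
    peptide missingness 0.10, protein missingness 0.05, Jaccard grouping 0.4,
    responder reduction 0.5.
    """

    output_dir: str = "results/pipeline"
    seed: int = 0
    simulate: SimConfig | None = field(default_factory=SimConfig)
    behavioral_path: str | None = None
    peptides_qvalue_path: str | None = None
    peptides_qvalue_sparse_path: str | None = None
    annotation_path: str | None = None
    excluded_samples: list[str] = field(default_factory=list)

    alpha: float = 0.05
    peptide_max_missing: float = 0.10
    protein_max_missing: float = 0.05
    jaccard_threshold: float = 0.4
    responder_threshold: float = 0.5
    n_imputations: int = 5
    svm_folds: int = 10
    svm_permutations: int = 10

    def validate(self) -> None:
        if self.simulate is None:
            paths = [self.behavioral_path, self.peptides_qvalue_path,
                     self.peptides_qvalue_sparse_path, self.annotation_path]
            missing = [p for p in paths if p is None or not Path(p).exists()]
            if missing:
                raise ValueError(f"input files not found: {missing}")
        else:
            self.simulate.validate()
        for name in ("alpha", "peptide_max_missing", "protein_max_missing",
                     "responder_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.jaccard_threshold <= 1:
            raise ValueError("jaccard_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        cfg.simulate = SimConfig(**sim) if isinstance(sim, dict) else None
        return cfg
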