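"""Synthetic study generator.

Produces complete synthetic trials with the statistical structure the
downstream analyses assume, so every stage of the pipeline is testable
end-to-end without any external download: a sex-stratified two-arm design
(placebo / no treatment), two days with a baseline and a post-vection
measurement each, placebo effects on the Day-2 symptom rises (and on gastric
activity in females only), log-normal peptide intensities with proteotypic
peptide→protein structure, marked sex effects on protein abundance,
intensity-dependent (missing-not-at-random) cell masking in two extraction
variants, planted placebo-regulated proteins, planted responder-predictive
baseline proteins, and a term→protein annotation with planted enriched terms.

Every planted effect is recorded in a *truth ledger* so tests can score
recovery.  The generator is fully deterministic under its seed.

Default effect sizes were chosen so that the emulated behavioral analyses
land in the regime of the real trial: a Day-2 nausea-rise attenuation of 1.3
day-noise SDs yields a group F near 40 and roughly 65% vs 15% responders; the
motion-sickness effect of 0.85 SDs yields F near 15; the female-only gastric
effect of 0.65 SDs yields a within-female F near 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import classify_responders
from .config import SimConfig
from .matrix import PeptideMatrix, sample_key
from . import io as pio

LN2 = float(np.log(2.0))


@dataclass
class StudyDesign:
    """Subject scaffold: arm and sex per subject, 2 days × 2 measurements."""

    subjects: pd.DataFrame  # index subject_id; columns arm, sex

    @property
    def sample_keys(self) -> list[str]:
        return [
            sample_key(s, d, m)
            for s in self.subjects.index
            for d in (1, 2)
            for m in (1, 2)
        ]


@dataclass
class SyntheticStudy:
    design: StudyDesign
    behavior: pd.DataFrame  # long by measure: subject, arm, sex, measure, m11..m22
    peptides_qvalue: PeptideMatrix
    peptides_qvalue_sparse: PeptideMatrix
    annotation: dict[str, set[str]]
    truth: dict
    config: SimConfig


def _make_design(cfg: SimConfig) -> StudyDesign:
    rows = []
    for arm, n in (("placebo", cfg.n_placebo), ("control", cfg.n_control)):
        n_female = int(round(n * cfg.sex_ratio))
        rows += [(arm, "f")] * n_female + [(arm, "m")] * (n - n_female)
    subjects = pd.DataFrame(rows, columns=["arm", "sex"])
    subjects.index = [f"S{i + 1:03d}" for i in range(len(subjects))]
    subjects.index.name = "subject"
    return StudyDesign(subjects=subjects)


def _simulate_behavior(cfg: SimConfig, design: StudyDesign,
                       rng: np.random.Generator) -> pd.DataFrame:
    sub = design.subjects
    n = len(sub)
    placebo = (sub["arm"] == "placebo").to_numpy()
    female = (sub["sex"] == "f").to_numpy()
    rows = []

    def bounded(x, hi):
        return np.clip(np.round(x), 0, hi)

    # Nausea (NRS 0–10): every subject passed a ≥5/10 screen on Day 1, so the
    # Day-1 vection rise is drawn ≥5; Day 2 adds day-to-day noise, a small
    # habituation drop, and the placebo attenuation in the treated arm.
    base1 = bounded(np.abs(rng.normal(0.8, 0.7, n)), 3)
    base2 = bounded(np.abs(rng.normal(0.8, 0.7, n)), 3)
    rise1 = np.maximum(rng.normal(6.5, 1.0, n), 5.0)
    rise2 = (
        rise1
        - 0.5
        + rng.normal(0.0, cfg.nausea_day_sd, n)
        - placebo * cfg.placebo_effect_nausea * cfg.nausea_day_sd
    )
    m11, m12 = base1, bounded(base1 + rise1, 10)
    m21, m22 = base2, bounded(base2 + np.maximum(rise2, 0), 10)
    rows.append(pd.DataFrame({"measure": "nausea", "m11": m11, "m12": m12,
                              "m21": m21, "m22": m22}, index=sub.index))

    # Motion sickness (SSMS sum 0–18), same latent structure, milder effect.
    base1 = bounded(np.abs(rng.normal(1.0, 0.8, n)), 4)
    base2 = bounded(np.abs(rng.normal(1.0, 0.8, n)), 4)
    rise1 = np.maximum(rng.normal(7.0, 1.5, n), 3.0)
    rise2 = (
        rise1
        - 0.5
        + rng.normal(0.0, cfg.ms_day_sd, n)
        - placebo * cfg.placebo_effect_ms * cfg.ms_day_sd
    )
    rows.append(pd.DataFrame({"measure": "ms", "m11": base1,
                              "m12": bounded(base1 + rise1, 18),
                              "m21": base2,
                              "m22": bounded(base2 + np.maximum(rise2, 0), 18)},
                             index=sub.index))

    # log-NTT: vection lowers the normo-to-tachy ratio; the placebo attenuates
    # the Day-2 drop in females only.  Values are continuous (log scale).
    b1 = rng.normal(0.8, 0.5, n)
    b2 = b1 + rng.normal(0.0, 0.2, n)
    drop1 = rng.normal(1.0, 0.3, n)
    drop2 = (
        drop1
        + rng.normal(0.0, cfg.ntt_day_sd, n)
        - (placebo & female) * cfg.placebo_effect_ntt_female * cfg.ntt_day_sd
    )
    rows.append(pd.DataFrame({"measure": "ntt", "m11": b1, "m12": b1 - drop1,
                              "m21": b2, "m22": b2 - drop2}, index=sub.index))

    behavior = pd.concat(rows).reset_index()
    behavior.insert(1, "arm", behavior["subject"].map(sub["arm"]))
    behavior.insert(2, "sex", behavior["subject"].map(sub["sex"]))
    return behavior[["subject", "arm", "sex", "measure", "m11", "m12", "m21", "m22"]]


def _calibrate_mnar_midpoint(x: np.ndarray, steepness: float, target: float) -> float:
    """Bisection for the logistic midpoint giving the target mean missing rate.

    Missingness probability is logistic in −intensity: low-abundance cells
    are more likely to drop out, the DIA-typical pattern.
    """
    if target <= 0:
        return -np.inf

    def mean_rate(x0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(steepness * (x - x0)))))

    lo, hi = x.min() - 50.0, x.max() + 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(cfg: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study (design, behavior, peptides, annotation)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    design = _make_design(cfg)
    behavior = _simulate_behavior(cfg, design, rng)
    sub = design.subjects
    n_sub = len(sub)
    samples = design.sample_keys
    n_samp = len(samples)

    # responder status (nausea) drives the planted baseline signal
    nb = behavior[behavior["measure"] == "nausea"].set_index("subject").loc[sub.index]
    responder = classify_responders(nb["m11"], nb["m12"], nb["m21"], nb["m22"])
    responder = pd.Series(responder, index=sub.index)

    # ---- proteome structure ------------------------------------------------
    protein_ids = np.array([f"P{i + 1:04d}" for i in range(cfg.n_proteins)])
    p_geom = min(1.0, 1.0 / cfg.peptides_per_protein_mean)
    n_pep = np.clip(rng.geometric(p_geom, cfg.n_proteins), 1,
                    cfg.peptides_per_protein_max)
    pep_protein_idx = np.repeat(np.arange(cfg.n_proteins), n_pep)
    peptide_ids = np.array([
        f"{protein_ids[p]}_pep{j + 1}"
        for p, k in zip(range(cfg.n_proteins), n_pep)
        for j in range(k)
    ])
    total_pep = len(peptide_ids)

    n_reg = int(round(cfg.frac_placebo_regulated_proteins * cfg.n_proteins))
    n_resp = int(round(cfg.frac_responder_predictive_proteins * cfg.n_proteins))
    special = rng.choice(cfg.n_proteins, size=n_reg + n_resp, replace=False)
    reg_idx, resp_idx = special[:n_reg], special[n_reg:]
    reg_sign = rng.choice([-1.0, 1.0], n_reg)
    resp_sign = rng.choice([-1.0, 1.0], n_resp)
    n_sexp = int(round(cfg.frac_sex_affected_proteins * cfg.n_proteins))
    sex_idx = rng.choice(cfg.n_proteins, size=n_sexp, replace=False)
    sex_sign = rng.choice([-1.0, 1.0], n_sexp)

    mu = rng.normal(cfg.protein_mean_log, cfg.protein_sd_log, cfg.n_proteins)
    pep_offset = rng.normal(0.0, cfg.peptide_offset_sd, total_pep)
    subject_eff = rng.normal(0.0, cfg.subject_sd, n_sub)

    # protein × sample effect matrix (log scale)
    placebo = (sub["arm"] == "placebo").to_numpy()
    female = (sub["sex"] == "f").to_numpy()
    is_resp = (responder.to_numpy() == 1.0) & placebo
    # sample axis order matches design.sample_keys: subject-major, then day, meas
    day = np.tile([1, 1, 2, 2], n_sub)
    meas = np.tile([1, 2, 1, 2], n_sub)
    subj_of_samp = np.repeat(np.arange(n_sub), 4)

    E = np.zeros((cfg.n_proteins, n_samp))
    E[sex_idx] += np.outer(sex_sign * cfg.sex_effect_sd, female[subj_of_samp])
    reg_cells = (placebo[subj_of_samp]) & (day == 2) & (meas == 2)
    E[reg_idx] += np.outer(reg_sign * cfg.placebo_log2_fold_change * LN2, reg_cells)
    resp_cells = (is_resp[subj_of_samp]) & (day == 2) & (meas == 1)
    E[resp_idx] += np.outer(resp_sign * cfg.responder_shift_sd, resp_cells)
    E += subject_eff[subj_of_samp][None, :]

    log_int = (
        mu[pep_protein_idx][:, None]
        + pep_offset[:, None]
        + E[pep_protein_idx]
        + rng.normal(0.0, cfg.noise_sd, (total_pep, n_samp))
    )
    intensities = np.exp(log_int)

    # ---- MNAR masking ------------------------------------------------------
    x0 = _calibrate_mnar_midpoint(log_int.ravel(), cfg.mnar_steepness,
                                  cfg.missing_target_rate)
    p_miss = 1.0 / (1.0 + np.exp(cfg.mnar_steepness * (log_int - x0)))
    masked = rng.random(log_int.shape) < p_miss
    unmask = rng.random(log_int.shape) < cfg.sparse_unmask_fraction
    masked_sparse = masked & ~unmask

    qv = np.where(masked, np.nan, intensities)
    qvs = np.where(masked_sparse, np.nan, intensities)

    mapping = pd.Series(protein_ids[pep_protein_idx], index=peptide_ids,
                        name="protein_id")
    mapping.index.name = "peptide_id"
    pep_qv = PeptideMatrix(
        intensities=pd.DataFrame(qv, index=pd.Index(peptide_ids, name="peptide_id"),
                                 columns=samples),
        mapping=mapping, provenance="qvalue",
    )
    pep_qvs = PeptideMatrix(
        intensities=pd.DataFrame(qvs, index=pd.Index(peptide_ids, name="peptide_id"),
                                 columns=samples),
        mapping=mapping, provenance="qvalue_sparse",
    )

    # ---- annotation with planted enriched terms ----------------------------
    annotation: dict[str, set[str]] = {}
    enriched_terms = []
    reg_set = protein_ids[reg_idx]
    for t in range(cfg.n_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(cfg.term_size_min, cfg.term_size_max + 1))
        size = min(size, cfg.n_proteins)  # tiny proteomes: cap at universe
        if t < cfg.n_enriched_terms and n_reg > 0:
            n_from_reg = min(int(round(cfg.enriched_term_regulated_fraction * size)),
                             n_reg)
            members = set(rng.choice(reg_set, n_from_reg, replace=False))
            others = np.setdiff1d(protein_ids, list(members))
            members |= set(rng.choice(others, size - len(members), replace=False))
            enriched_terms.append(term)
        else:
            members = set(rng.choice(protein_ids, size, replace=False))
        annotation[term] = members

    truth = {
        "regulated_proteins": {
            str(protein_ids[i]): float(s) * cfg.placebo_log2_fold_change
            for i, s in zip(reg_idx, reg_sign)
        },
        "responder_proteins": {
            str(protein_ids[i]): float(s) * cfg.responder_shift_sd
            for i, s in zip(resp_idx, resp_sign)
        },
        "sex_proteins": {
            str(protein_ids[i]): float(s) * cfg.sex_effect_sd
            for i, s in zip(sex_idx, sex_sign)
        },
        "enriched_terms": enriched_terms,
        "responder_nausea": {
            s: (None if np.isnan(v) else bool(v))
            for s, v in responder.items()
        },
        "masked_fraction_qvalue": float(masked.mean()),
        "masked_fraction_qvalue_sparse": float(masked_sparse.mean()),
    }

    return SyntheticStudy(
        design=design, behavior=behavior, peptides_qvalue=pep_qv,
        peptides_qvalue_sparse=pep_qvs, annotation=annotation, truth=truth,
        config=cfg,
    )


FIXTURE_FILES = (
    "behavior.tsv",
    "peptides_qvalue.tsv",
    "peptides_qvalue_sparse.tsv",
    "peptide_mapping.tsv",
    "annotation.tsv",
    "truth.json",
    "config.yaml",
)


def write_fixtures(study: SyntheticStudy, directory) -> list[str]:
    """Write the study as TSV/JSON/YAML fixtures; returns the file manifest.

    The files round-trip losslessly through the readers in :mod:`.io`
    (missing cells stay missing).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pio.write_behavior_tsv(study.behavior, directory / "behavior.tsv")
    pio.write_peptide_tsv(study.peptides_qvalue, directory / "peptides_qvalue.tsv")
    pio.write_peptide_tsv(study.peptides_qvalue_sparse,
                          directory / "peptides_qvalue_sparse.tsv")
    pio.write_mapping_tsv(study.peptides_qvalue.mapping,
                          directory / "peptide_mapping.tsv")
    pio.write_annotation_tsv(study.annotation, directory / "annotation.tsv")
    pio.write_json(study.truth, directory / "truth.json")
    study.config.to_yaml(directory / "config.yaml")
    return list(FIXTURE_FILES)


def plant_variance_response(
    das: np.ndarray,
    arm: np.ndarray,
    sex: np.ndarray,
    fractions: dict[tuple[str, ...], float],
    seed: int,
) -> np.ndarray:
    """A response with a prescribed per-term explained-variance composition.

    ``fractions`` maps model terms (tuples over ``"das"``, ``"grp"``,
    ``"sex"``) to the variance share each should explain; the remainder is
    i.i.d. Gaussian noise.  Term columns are orthogonalized against the
    intercept and against each other (in the given order) before planting,
    so the prescribed composition is well defined even when the sampled
    predictors are incidentally correlated (e.g. a chance DAS–group
    correlation in one study draw); the Type II attribution of the
    variance-dissection model then recovers the planted shares.
    """
    rng = np.random.default_rng(seed)
    total = sum(fractions.values())
    if not 0 <= total <= 1:
        raise ValueError("planted fractions must sum to at most 1")
    cols = {
        "das": np.asarray(das, dtype=float),
        "grp": np.where(np.asarray(arm) == "placebo", 0.5, -0.5),
        "sex": np.where(np.asarray(sex) == "f", 0.5, -0.5),
    }
    n = len(cols["das"])
    y = np.zeros(n)
    basis: list[np.ndarray] = []
    for term, frac in fractions.items():
        x = np.ones(n)
        for name in term:
            x = x * cols[name]
        x = x - x.mean()
        for b in basis:
            x = x - (x @ b) * b
        norm = np.linalg.norm(x)
        if norm < 1e-10 * np.sqrt(n):
            raise ValueError(f"term {term} is collinear with earlier terms")
        x = x / norm
        basis.append(x)
        y = y + np.sqrt(frac * n) * x
    y = y + np.sqrt(1.0 - total) * rng.standard_normal(n)
    return y
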