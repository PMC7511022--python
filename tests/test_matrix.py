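"""Matrix construction: filters, aggregation, fill-in, normalization, folds."""

import numpy as np
import pandas as pd
import pytest

from placeboprot.matrix import (
    PeptideMatrix,
    ProteinMatrix,
    aggregate_to_proteins,
    drop_samples,
    fill_and_filter,
    filter_peptides,
    fold_changes,
    normalize_and_log,
    normalized_scale,
    parse_sample_key,
    sample_key,
)


def toy_peptides(values, mapping=None, columns=None):
    values = np.asarray(values, dtype=float)
    n_pep, n_samp = values.shape
    index = [f"pep{i}" for i in range(n_pep)]
    columns = columns or [sample_key(f"S{j:03d}", 1, 1) for j in range(n_samp)]
    mapping = mapping or {f"pep{i}": f"P{i}" for i in range(n_pep)}
    return PeptideMatrix(
        intensities=pd.DataFrame(values, index=index, columns=columns),
        mapping=pd.Series(mapping),
    )


class TestFilterPeptides:
    def test_ten_percent_boundary(self):
        nan = np.nan
        row_10pct = [1.0] * 9 + [nan]
        row_20pct = [1.0] * 8 + [nan, nan]
        m = toy_peptides([row_10pct, row_20pct])
        kept = filter_peptides(m, 0.10)
        assert list(kept.intensities.index) == ["pep0"]  # 10% kept, 20% removed

    def test_fully_observed_identity(self):
        m = toy_peptides(np.ones((3, 5)))
        kept = filter_peptides(m)
        pd.testing.assert_frame_equal(kept.intensities, m.intensities)

    def test_survivor_count_matches_brute_force(self, study):
        m = study.peptides_qvalue
        kept = filter_peptides(m, 0.10)
        brute = sum(
            1 for _, row in m.intensities.iterrows()
            if row.isna().sum() / len(row) <= 0.10
        )
        assert len(kept.intensities) == brute

    def test_all_removed_errors_with_counts(self):
        m = toy_peptides(np.full((2, 4), np.nan))
        with pytest.raises(ValueError, match="2 peptides"):
            filter_peptides(m)


class TestAggregate:
    def test_sum_and_missing_rules(self):
        m = toy_peptides(
            [[3.0, np.nan, np.nan], [5.0, 2.0, np.nan]],
            mapping={"pep0": "A", "pep1": "A"},
        )
        prot = aggregate_to_proteins(m)
        row = prot.intensities.loc["A"]
        assert row.iloc[0] == 8.0  # both observed: sum
        assert row.iloc[1] == 2.0  # one missing: sum of observed
        assert np.isnan(row.iloc[2])  # all missing: missing

    def test_hand_aggregation_on_three_by_three(self):
        vals = [[1.0, 2.0, np.nan], [4.0, np.nan, 6.0], [7.0, 8.0, 9.0]]
        m = toy_peptides(vals, mapping={"pep0": "A", "pep1": "A", "pep2": "B"})
        prot = aggregate_to_proteins(m).intensities
        np.testing.assert_allclose(prot.loc["A"], [5.0, 2.0, 6.0])
        np.testing.assert_allclose(prot.loc["B"], [7.0, 8.0, 9.0])

    def test_unmapped_peptide_rejected(self):
        m = toy_peptides(np.ones((2, 2)))
        m.mapping = m.mapping.drop("pep1")
        with pytest.raises(ValueError, match="without protein mapping"):
            aggregate_to_proteins(m)


class TestFillAndFilter:
    @staticmethod
    def _pair(qv_vals, qvs_vals):
        cols = [sample_key(f"S{j:03d}", 1, 1) for j in range(len(qv_vals[0]))]
        idx = [f"P{i}" for i in range(len(qv_vals))]
        qv = ProteinMatrix(pd.DataFrame(qv_vals, index=idx, columns=cols,
                                        dtype=float))
        qvs = ProteinMatrix(pd.DataFrame(qvs_vals, index=idx, columns=cols,
                                         dtype=float))
        return qv, qvs

    def test_fill_from_sparse(self):
        qv, qvs = self._pair([[np.nan, 2.0]], [[7.0, 2.0]])
        out = fill_and_filter(qv, qvs, max_missing=0.5)
        assert out.intensities.iloc[0, 0] == 7.0

    def test_missing_in_both_counts_toward_threshold(self):
        nan = np.nan
        qv, qvs = self._pair([[nan] + [1.0] * 9], [[nan] + [1.0] * 9])
        # 10% missing after fill > 5% → removed → everything gone → error
        with pytest.raises(ValueError, match="exceed"):
            fill_and_filter(qv, qvs, max_missing=0.05)

    def test_five_percent_boundary(self):
        nan = np.nan
        row_5pct = [nan] + [1.0] * 19  # 1/20 = 5%: kept
        row_10pct = [nan, nan] + [1.0] * 18  # 10%: removed
        qv, qvs = self._pair([row_5pct, row_10pct], [row_5pct, row_10pct])
        out = fill_and_filter(qv, qvs, max_missing=0.05)
        assert list(out.intensities.index) == ["P0"]

    def test_shape_mismatch_rejected(self):
        qv, _ = self._pair([[1.0, 2.0]], [[1.0, 2.0]])
        _, qvs = self._pair([[1.0, 2.0], [3.0, 4.0]], [[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="differ"):
            fill_and_filter(qv, qvs)

    def test_deletions_match_brute_force(self, study):
        qv = aggregate_to_proteins(study.peptides_qvalue)
        qvs = aggregate_to_proteins(study.peptides_qvalue_sparse)
        out = fill_and_filter(qv, qvs, 0.05)
        filled = qv.intensities.where(~qv.intensities.isna(), qvs.intensities)
        brute = sum(
            1 for _, row in filled.iterrows()
            if row.isna().sum() / len(row) <= 0.05
        )
        assert len(out.intensities) == brute


class TestNormalizeAndLog:
    def test_column_medians_one_prelog(self):
        m = ProteinMatrix(pd.DataFrame(
            np.random.default_rng(0).lognormal(0, 1, (11, 4)),
            index=[f"P{i}" for i in range(11)],
            columns=[sample_key(f"S{j:03d}", 1, 1) for j in range(4)]))
        pre = normalized_scale(m)
        np.testing.assert_allclose(pre.median(axis=0), 1.0)

    def test_ln_values_of_simple_column(self):
        m = ProteinMatrix(pd.DataFrame(
            {"S000_1_1": [2.0, 4.0, 8.0]}, index=["a", "b", "c"]))
        out = normalize_and_log(m)
        np.testing.assert_allclose(out.intensities["S000_1_1"],
                                   [-0.693147, 0.0, 0.693147], atol=1e-5)
        assert out.normalized and out.logged

    def test_column_scaling_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, (9, 3))
        m1 = ProteinMatrix(pd.DataFrame(vals.copy()))
        scaled = vals.copy()
        scaled[:, 1] *= 10.0
        m2 = ProteinMatrix(pd.DataFrame(scaled))
        pd.testing.assert_frame_equal(normalize_and_log(m1).intensities,
                                      normalize_and_log(m2).intensities)

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        m = ProteinMatrix(pd.DataFrame(rng.lognormal(0, 1, (15, 3))))
        once = normalized_scale(m)
        twice = normalized_scale(ProteinMatrix(once))
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_median_rejected(self):
        m = ProteinMatrix(pd.DataFrame({"S000_1_1": [0.0, 0.0, 1.0]}))
        with pytest.raises(ValueError, match="median"):
            normalize_and_log(m)


class TestFoldChanges:
    @staticmethod
    def _matrix(i1, i2):
        cols = [sample_key("S001", 1, 1), sample_key("S001", 1, 2)]
        return pd.DataFrame([[i1, i2]], index=["P1"], columns=cols)

    def test_equal_measurements_zero(self):
        fc = fold_changes(self._matrix(5.0, 5.0))
        assert fc.values.iloc[0, 0] == 0.0

    def test_fourfold_is_two(self):
        fc = fold_changes(self._matrix(2.0, 8.0))
        assert fc.values.iloc[0, 0] == 2.0

    def test_missing_measurement_propagates(self):
        fc = fold_changes(self._matrix(np.nan, 8.0))
        assert np.isnan(fc.values.iloc[0, 0])

    def test_planted_placebo_doubling_visible(self, study, protein_data):
        fc2 = protein_data["fc"].day(2)
        placebo = [s for s in fc2.columns
                   if study.design.subjects.loc[s, "arm"] == "placebo"]
        for pid, lfc in study.truth["regulated_proteins"].items():
            if pid in fc2.index:
                observed = fc2.loc[pid, placebo].mean()
                assert observed == pytest.approx(lfc, abs=0.4)

    def test_aggregation_commutes_with_fold_change_on_toys(self):
        cols = [sample_key("S001", 1, 1), sample_key("S001", 1, 2)]
        m = toy_peptides([[2.0, 8.0], [6.0, 8.0]],
                         mapping={"pep0": "A", "pep1": "A"}, columns=cols)
        prot = aggregate_to_proteins(m)
        fc_of_sum = fold_changes(prot.intensities).values.iloc[0, 0]
        assert fc_of_sum == pytest.approx(np.log2(16.0 / 8.0))


def test_drop_samples_explicit_only(study):
    key = study.peptides_qvalue.intensities.columns[0]
    dropped = drop_samples(study.peptides_qvalue, [key])
    assert key not in dropped.intensities.columns
    with pytest.raises(ValueError, match="not in matrix"):
        drop_samples(study.peptides_qvalue, ["nope_1_1"])


def test_sample_key_roundtrip():
    assert parse_sample_key(sample_key("S007", 2, 1)) == ("S007", 2, 1)
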