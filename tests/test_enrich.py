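"""Hypergeometric enrichment, Jaccard clustering, GO-signature regression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from placeboprot.enrich import (
    enrich,
    go_term_predict_das,
    jaccard_cluster,
    jaccard_index,
)


def brute_force_tail(N, K, n, k):
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / total
        for i in range(k, min(K, n) + 1)
    )


class TestEnrichment:
    def test_closed_form_example(self):
        background = {f"p{i}" for i in range(10)}
        term = {"p0", "p1", "p2"}
        study = {"p0", "p1", "p2"}
        out = enrich(study, {"T": term}, background)
        assert out.loc["T", "p"] == pytest.approx(1 / 120, abs=1e-12)

    def test_no_hits_gives_p_one(self):
        background = {f"p{i}" for i in range(10)}
        out = enrich({"p9"}, {"T": {"p0", "p1"}}, background)
        assert out.loc["T", "p"] == 1.0

    def test_p_monotone_decreasing_in_hits(self):
        from scipy import stats

        N, K, n = 50, 10, 12
        ps = [float(stats.hypergeom.sf(k - 1, N, K, n))
              for k in range(0, min(K, n) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside background"):
            enrich({"zzz"}, {"T": {"a"}}, {"a", "b"})

    def test_fully_redundant_terms_collapse(self):
        background = {f"p{i}" for i in range(8)}
        ann = {"T2": {"p0", "p1"}, "T1": {"p0", "p1"}, "T3": {"p2"}}
        out = enrich({"p0", "p1"}, ann, background)
        assert "T1" in out.index and "T2" not in out.index
        assert out.loc["T1", "collapsed_terms"] == "T2"

    def test_unannotated_protein_does_not_change_p(self):
        background = {f"p{i}" for i in range(10)}
        ann = {"T": {"p0", "p1", "p2"}}
        base = enrich({"p0", "p1"}, ann, background)
        # removing an unannotated protein from background changes N, so
        # instead drop it from the study: p depends only on (N, K, n, k)
        with_extra = enrich({"p0", "p1", "p9"}, ann, background)
        assert base.loc["T", "k"] == with_extra.loc["T", "k"]

    def test_null_p_values_approximately_uniform(self):
        """Random study sets: the discrete p-value is stochastically ≥ uniform
        (exceedance at most nominal), checked at several thresholds."""
        rng = np.random.default_rng(0)
        background = [f"p{i}" for i in range(40)]
        term = set(background[:8])
        ps = []
        for _ in range(500):
            study = set(rng.choice(background, 10, replace=False))
            out = enrich(study, {"T": term}, set(background))
            ps.append(out.loc["T", "p"])
        ps = np.array(ps)
        for thr in (0.05, 0.1, 0.25, 0.5):
            assert (ps <= thr).mean() <= thr + 0.03


class TestJaccard:
    def test_pairwise_example(self):
        assert jaccard_index({"a", "b", "c"}, {"b", "c"}) == pytest.approx(2 / 3)
        clusters = jaccard_cluster({"T1": {"a", "b", "c"}, "T2": {"b", "c"}})
        assert clusters["T1"] == clusters["T2"]

    def test_disjoint_sets_separate(self):
        clusters = jaccard_cluster({"T1": {"a"}, "T2": {"b"}})
        assert clusters["T1"] != clusters["T2"]

    def test_matches_brute_force_union_find(self):
        rng = np.random.default_rng(1)
        universe = [f"p{i}" for i in range(15)]
        for _ in range(50):
            n_terms = rng.integers(3, 8)
            sets = {
                f"T{j}": set(rng.choice(universe, rng.integers(2, 8),
                                        replace=False))
                for j in range(n_terms)
            }
            ours = jaccard_cluster(sets, 0.4)
            # oracle: grow components by repeated closure over pairwise J
            comp = {t: {t} for t in sets}
            for a, b in itertools.combinations(sets, 2):
                if jaccard_index(sets[a], sets[b]) > 0.4:
                    merged = comp[a] | comp[b]
                    for t in merged:
                        comp[t] = merged
            for a, b in itertools.combinations(sets, 2):
                assert (ours[a] == ours[b]) == (b in comp[a])

    def test_invariant_to_input_order(self):
        sets = {"T1": {"a", "b"}, "T2": {"b", "c"}, "T3": {"x"}}
        a = jaccard_cluster(dict(sorted(sets.items())))
        b = jaccard_cluster(dict(sorted(sets.items(), reverse=True)))
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_threshold_one_gives_singletons_unless_identical(self):
        sets = {"T1": {"a", "b"}, "T2": {"a", "b"}, "T3": {"a", "c"}}
        clusters = jaccard_cluster(sets, threshold=1.0)
        assert clusters["T1"] != clusters["T3"]
        # J = 1 is not > 1, so even identical sets stay separate clusters
        assert clusters["T1"] != clusters["T2"]


class TestGoTermDasRegression:
    @staticmethod
    def _fixture(seed=0, n=60, signal=True):
        rng = np.random.default_rng(seed)
        subjects = [f"S{i:03d}" for i in range(n)]
        arm = pd.Series(["placebo"] * (n // 2) + ["control"] * (n // 2),
                        index=subjects)
        fc = pd.DataFrame(rng.standard_normal((6, n)),
                          index=[f"P{i}" for i in range(6)], columns=subjects)
        if signal:
            das = 1.0 * fc.loc["P0"] + 0.5 * fc.loc["P1"] - 0.8 * fc.loc["P2"]
        else:
            das = pd.Series(rng.standard_normal(n), index=subjects)
        return das, fc, arm

    def test_exact_linear_combination_r2_one(self):
        das, fc, arm = self._fixture(signal=True)
        out = go_term_predict_das(das, fc, {"T": {"P0", "P1", "P2"}}, arm)
        for arm_name in ("placebo", "control"):
            assert out.loc[("T", arm_name), "r2"] == pytest.approx(1.0, abs=1e-9)

    def test_null_das_rarely_fdr_significant(self):
        """Permuted (independent) DAS: few FDR-significant term models.

        The bisquare outlier pre-pass makes the F-test mildly anti-
        conservative at 30 subjects per arm, so the bound here allows a
        small excess over the nominal level.
        """
        hits = total = 0
        for seed in range(40):
            das, fc, arm = self._fixture(seed=seed, signal=False)
            terms = {f"T{j}": {f"P{i}" for i in range(j, j + 3)}
                     for j in range(4)}
            out = go_term_predict_das(das, fc, terms, arm)
            fitted = out["fdr_model"].dropna()
            hits += (fitted <= 0.05).sum()
            total += len(fitted)
        assert hits / total <= 0.08

    def test_oversized_term_skipped(self):
        das, fc, arm = self._fixture()
        small_arm = arm.copy()
        out = go_term_predict_das(
            das.iloc[:8], fc.iloc[:, :8], {"T": set(fc.index)},
            small_arm.iloc[:8])
        assert out["skipped"].notna().any()

    def test_arm_specific_signal_detected(self):
        """A term driving the DAS in the placebo arm only yields a smaller
        placebo-arm model p in the vast majority of runs."""
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(100 + seed)
            n = 80
            subjects = [f"S{i:03d}" for i in range(n)]
            arm = pd.Series(["placebo"] * 40 + ["control"] * 40, index=subjects)
            fc = pd.DataFrame(rng.standard_normal((3, n)),
                              index=["P0", "P1", "P2"], columns=subjects)
            das = pd.Series(rng.standard_normal(n) * 0.5, index=subjects)
            in_placebo = (arm == "placebo").to_numpy()
            das[in_placebo] += fc.loc["P0", in_placebo] + fc.loc["P1", in_placebo]
            out = go_term_predict_das(das, fc, {"T": {"P0", "P1", "P2"}}, arm)
            wins += (out.loc[("T", "placebo"), "p_model"]
                     < out.loc[("T", "control"), "p_model"])
        assert wins / n_runs >= 0.9
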