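"""Discovery engine: filtering, dominant encoding, screening, structure models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polybrix import (
    CausalAllele,
    SimConfig,
    bh_adjust,
    datasets,
    encode_presence_absence,
    filter_loci,
    fit_model1,
    fit_model2,
    infer_structure_groups,
    screen_alleles,
    select_diagnostic_alleles,
    simulate_cohort,
    welch_screen,
)
from tests.conftest import make_table, random_table


# ---------------------------------------------------------------------------
# filtering and encoding against exhaustive oracles
# ---------------------------------------------------------------------------

class TestFilterLoci:
    def test_twenty_percent_missing_is_removed_strictly(self):
        calls = [[(0, 0, 1, 1)] * 8 + [None, None]]  # 2/10 missing = 20%
        table = make_table([("Ro01", 1, "A", ("T",))], calls,
                           [f"s{i}" for i in range(10)])
        out, stats_ = filter_loci(table)
        assert out.n_loci == 0 and stats_.n_removed_missing == 1

    def test_allele_count_bounds(self):
        table = make_table(
            [
                ("Ro01", 1, "A", ("T",)),   # monomorphic in calls
                ("Ro01", 2, "A", ("C", "G", "T", "AA")),  # 5 observed
                ("Ro01", 3, "A", ("T",)),   # biallelic, kept
            ],
            [
                [(0, 0, 0, 0)] * 4,
                [(0, 1, 2, 3), (0, 1, 2, 4), (0, 0, 0, 0), (1, 2, 3, 4)],
                [(0, 0, 1, 1)] * 4,
            ],
            ["s1", "s2", "s3", "s4"],
        )
        out, stats_ = filter_loci(table)
        assert list(out.loci.index) == ["Ro01:3"]
        assert stats_.n_removed_allele_count == 2

    def test_matches_bruteforce_per_locus_scan(self):
        rng = np.random.default_rng(7)
        table = random_table(rng, n_loci=100, n_samples=10, missing_rate=0.25)
        out, _ = filter_loci(table)
        expected = []
        for i, locus in enumerate(table.loci.index):
            cells = [table.calls[i, s] for s in range(10)]
            miss = sum(c is None for c in cells) / 10
            observed = {a for c in cells if c is not None for a in c}
            if miss < 0.20 and 2 <= len(observed) <= 4:
                expected.append(locus)
        assert list(out.loci.index) == expected


class TestEncodePresenceAbsence:
    def test_dosage_is_discarded(self):
        table = make_table(
            [("Ro01", 1, "A", ("T",))],
            [[(0, 0, 1, 1), (0, 0, 0, 1), (1, 1, 1, 1), None]],
            ["s1", "s2", "s3", "s4"],
        )
        m = encode_presence_absence(table)
        assert list(m.columns) == [("Ro01:1", "A"), ("Ro01:1", "T")]
        assert m[("Ro01:1", "A")].tolist()[:3] == [1.0, 1.0, 0.0]
        assert m[("Ro01:1", "T")].tolist()[:3] == [1.0, 1.0, 1.0]
        assert m.iloc[3].isna().all()  # missing cell hits every column

    def test_matches_bruteforce_membership(self):
        rng = np.random.default_rng(8)
        table = random_table(rng, n_loci=50, n_samples=20, missing_rate=0.15)
        m = encode_presence_absence(table)
        for i, locus in enumerate(table.loci.index):
            names = table.allele_strings(i)
            for (loc, allele) in [c for c in m.columns if c[0] == locus]:
                a = names.index(allele)
                for s in range(20):
                    call = table.calls[i, s]
                    got = m.iloc[s][(loc, allele)]
                    if call is None:
                        assert np.isnan(got)
                    else:
                        assert got == float(a in call)

    def test_filtered_loci_contribute_at_least_two_columns(self):
        rng = np.random.default_rng(9)
        table, _ = filter_loci(random_table(rng, n_loci=60, n_samples=12))
        m = encode_presence_absence(table)
        per_locus = pd.Series([c[0] for c in m.columns]).value_counts()
        assert set(per_locus.index) == set(table.loci.index)
        assert (per_locus >= 2).all()


# ---------------------------------------------------------------------------
# Welch screen and BH correction
# ---------------------------------------------------------------------------

def matrix_from_columns(cols):
    samples = [f"s{i}" for i in range(len(next(iter(cols.values()))))]
    return pd.DataFrame(
        {("L", k): np.asarray(v, dtype=float) for k, v in cols.items()},
        index=pd.Index(samples, name="sample"),
    )


class TestWelchScreen:
    def test_identical_classes_give_null_statistics(self):
        m = matrix_from_columns({"a": [1, 1, 1, 0, 0, 0]})
        ssc = pd.Series([10, 11, 12, 10, 11, 12], index=m.index, dtype=float)
        res = welch_screen(m, ssc)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res["effect_brix"].iloc[0] == pytest.approx(0.0)

    def test_closed_form_example(self):
        # present {14,15,16}, absent {9,10,11}: t = 5*sqrt(3/2), df = 4
        m = matrix_from_columns({"a": [1, 1, 1, 0, 0, 0]})
        ssc = pd.Series([14, 15, 16, 9, 10, 11], index=m.index, dtype=float)
        res = welch_screen(m, ssc)
        assert res["t"].iloc[0] == pytest.approx(5 * np.sqrt(1.5), rel=1e-12)
        assert res["df"].iloc[0] == pytest.approx(4.0, rel=1e-12)
        expected_p = 2 * stats.t.sf(5 * np.sqrt(1.5), 4)
        assert res["p"].iloc[0] == pytest.approx(expected_p, rel=1e-12)

    def test_degenerate_columns_get_nan_not_exception(self):
        m = matrix_from_columns(
            {
                "all_present": [1.0] * 6,
                "tiny_class": [1, 0, 0, 0, 0, 0],
                "zero_variance": [1, 1, 1, 0, 0, 0],
            }
        )
        ssc = pd.Series([10.0] * 6, index=m.index)
        res = welch_screen(m, ssc)
        assert res["p"].isna().all()

    def test_matches_scipy_per_column(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 2, size=(30, 40)).astype(float)
        X[rng.random((30, 40)) < 0.1] = np.nan
        m = pd.DataFrame(
            X,
            index=[f"s{i}" for i in range(30)],
            columns=pd.MultiIndex.from_tuples(
                [("L", str(j)) for j in range(40)]
            ),
        )
        ssc = pd.Series(rng.normal(12, 2, 30), index=m.index)
        res = welch_screen(m, ssc, min_class_size=3)
        for j, col in enumerate(m.columns):
            x = m[col]
            a = ssc[x == 1.0]
            b = ssc[x == 0.0]
            if min(len(a), len(b)) < 3:
                assert np.isnan(res["p"].iloc[j])
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            if np.isnan(res["p"].iloc[j]):
                assert a.var() + b.var() == 0
            else:
                assert res["t"].iloc[j] == pytest.approx(t, rel=1e-10)
                assert res["p"].iloc[j] == pytest.approx(p, rel=1e-10)


def bh_bruteforce(p, alpha):
    """Literal step-up: find the largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    cutoff = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:cutoff]] = True
    # q-values: running minimum of m*p_(i)/i from the top
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, reject


class TestBHAdjust:
    def test_single_pvalue_family(self):
        q, sig = bh_adjust(pd.Series([0.04]), alpha=0.05)
        assert sig.iloc[0] and q.iloc[0] == pytest.approx(0.04)

    def test_hand_stepped_example(self):
        q, sig = bh_adjust(pd.Series([0.01, 0.02, 0.03, 0.9]), alpha=0.05)
        assert np.allclose(q[:3], 0.04) and q.iloc[3] == pytest.approx(0.9)
        assert sig.tolist() == [True, True, True, False]

    def test_nan_pvalues_excluded_from_family(self):
        q, sig = bh_adjust(pd.Series([0.04, np.nan]), alpha=0.05)
        assert sig.iloc[0] and not sig.iloc[1] and np.isnan(q.iloc[1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_agrees_with_bruteforce_stepup(self, ps, alpha):
        q, sig = bh_adjust(pd.Series(ps), alpha=alpha)
        q_ref, rej_ref = bh_bruteforce(ps, alpha)
        assert np.allclose(q.to_numpy(), q_ref)
        assert (sig.to_numpy() == rej_ref).all()
        # monotone after sorting, and q >= p
        p_arr = np.asarray(ps)
        assert (q.to_numpy() >= p_arr - 1e-15).all()
        order = np.argsort(p_arr)
        assert (np.diff(q.to_numpy()[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# structure inference
# ---------------------------------------------------------------------------

class TestStructureInference:
    def test_recovers_two_disjoint_groups(self):
        cfg = SimConfig(n_samples=30, n_loci=200, n_groups=2,
                        group_divergence=0.1, seed=21)
        coh = simulate_cohort(cfg)
        g = infer_structure_groups(coh.allele_matrix(), seed=0)
        assert g.k == 2
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(coh.group, g.labels) == 1.0

    def test_identical_rows_collapse_to_one_group(self):
        m = pd.DataFrame(
            np.ones((12, 20)),
            index=[f"s{i}" for i in range(12)],
            columns=pd.MultiIndex.from_tuples(
                [("L", str(j)) for j in range(20)]
            ),
        )
        g = infer_structure_groups(m, seed=0)
        assert g.k == 1 and g.labels.nunique() == 1

    def test_chosen_k_minimizes_bic(self):
        cfg = SimConfig(n_samples=36, n_loci=150, n_groups=3,
                        group_divergence=0.1, seed=22)
        coh = simulate_cohort(cfg)
        g = infer_structure_groups(coh.allele_matrix(), seed=1)
        assert g.bic[g.k] == min(g.bic.values())

    def test_external_grouping_from_cohort_fixture(self):
        meta = datasets.sequenced_samples()
        # published k-means groupings: 3 groups on one reference, 4 on the other
        assert meta["hv1_group"].nunique() == 3
        assert meta["rov3_group"].nunique() == 4


# ---------------------------------------------------------------------------
# nested structure-correction models
# ---------------------------------------------------------------------------

class TestModelFits:
    def test_single_group_interaction_flagged(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        fit = fit_model1(y, np.zeros(20), rng.integers(0, 2, 20).astype(float))
        assert fit.flag == "single_group" and np.isnan(fit.p)

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(2)
        n = 200
        group = np.repeat([0, 1], n // 2)
        allele = rng.integers(0, 2, n).astype(float)
        effect = np.where(group == 0, 2.0, -2.0) * allele
        y = 10 + effect + rng.normal(0, 0.5, n)
        fit = fit_model1(y, group, allele)
        assert fit.p < 0.001

    def test_homogeneous_effect_interaction_level_is_nominal(self):
        rng = np.random.default_rng(3)
        n, reps, hits = 80, 300, 0
        for _ in range(reps):
            group = np.repeat([0, 1], n // 2)
            allele = rng.integers(0, 2, n).astype(float)
            y = 10 + 1.0 * allele + rng.normal(0, 1, n)
            if fit_model1(y, group, allele).p <= 0.05:
                hits += 1
        half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) <= half

    def test_single_group_model2_equals_pooled_t_f(self):
        rng = np.random.default_rng(4)
        y = rng.normal(12, 2, 30)
        allele = rng.integers(0, 2, 30).astype(float)
        fit = fit_model2(y, np.zeros(30), allele)
        t, _ = stats.ttest_ind(y[allele == 1], y[allele == 0], equal_var=True)
        assert abs(fit.F - t**2) < 1e-9

    def test_model_f_tests_match_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 60
        group = rng.integers(0, 3, n)
        allele = rng.integers(0, 2, n).astype(float)
        y = 10 + 0.5 * allele + 0.3 * group + rng.normal(0, 1, n)
        D = pd.get_dummies(pd.Categorical(group), drop_first=True, dtype=float)
        X_red = sm.add_constant(pd.DataFrame({"a": allele}).join(D))
        X_full = X_red.join(D.mul(allele, axis=0).add_prefix("ix_"))
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_red).fit()
        F_ref, p_ref, _ = full.compare_f_test(red)
        fit = fit_model1(y, group, allele)
        assert fit.F == pytest.approx(F_ref, rel=1e-9)
        assert fit.p == pytest.approx(p_ref, rel=1e-9)

    def test_confounded_allele_is_inestimable(self):
        y = np.random.default_rng(6).normal(size=20)
        group = np.repeat([0, 1], 10)
        allele = (group == 0).astype(float)  # present <=> group 0
        fit = fit_model2(y, group, allele)
        assert fit.flag == "inestimable" and np.isnan(fit.p)

    def test_within_group_power_for_planted_effect(self):
        # +1.5 °Brix structure-independent allele, 2 groups, n=96: the
        # within-group term should reject at alpha=0.05 in >= 80% of runs
        hits, reps = 0, 120
        for r in range(reps):
            cfg = SimConfig(
                n_samples=96, n_loci=8, n_groups=2, residual_sd=1.5,
                causal_alleles=[CausalAllele(3, 1, 1.5)], seed=70_000 + r,
            )
            coh = simulate_cohort(cfg)
            col = coh.allele_matrix()[
                (coh.truth["locus"].iloc[0], coh.truth["allele"].iloc[0])
            ]
            if fit_model2(coh.mean_ssc(), coh.group, col).p <= 0.05:
                hits += 1
        assert hits / reps >= 0.8


# ---------------------------------------------------------------------------
# selection rule and pipeline determinism
# ---------------------------------------------------------------------------

def records_frame(rows):
    cols = ["q", "p_interaction", "interaction_flag", "p_within"]
    return pd.DataFrame(rows, columns=cols)


class TestSelection:
    def test_rule_applications(self):
        recs = records_frame(
            [
                (0.01, 0.6, None, 0.001),   # selected
                (0.01, 0.004, None, 0.001),  # structure-dependent: rejected
                (0.2, 0.6, None, 0.001),    # screen-insignificant: rejected
                (0.01, np.nan, "single_group", 0.001),  # selected
                (0.01, 0.6, None, np.nan),  # inestimable within: rejected
            ]
        )
        out = select_diagnostic_alleles(recs, alpha=0.05)
        assert out["selected"].tolist() == [True, False, False, True, False]

    def test_screen_is_deterministic_for_fixed_seed(self):
        cfg = SimConfig(n_samples=40, n_loci=100, n_groups=2, seed=30,
                        causal_alleles=[CausalAllele(5, 1, 2.0)])
        coh = simulate_cohort(cfg)
        m, ssc = coh.allele_matrix(), coh.mean_ssc()
        a = screen_alleles(m, ssc, coh.group)
        b = screen_alleles(m, ssc, coh.group)
        pd.testing.assert_frame_equal(a, b)
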