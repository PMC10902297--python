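"""Group contrasts, median splits, cognition regressions and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from neuroplex import (
    MultiplexNetwork,
    cognition_regression,
    fdr_bh,
    group_contrast,
    layer_contribution,
    median_split,
    summary_ttest,
    unimodal_baseline,
)


def _cohort(n1=20, n2=20, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n1 + n2)],
            "group": ["young"] * n1 + ["old"] * n2,
            "education": rng.normal(20, 3, n1 + n2),
            "grey_matter_volume": rng.normal(6e5, 5e4, n1 + n2),
        }
    )


class TestSummaryTtest:
    def test_equal_means_give_zero(self):
        assert summary_ttest(5.0, 1.0, 30, 5.0, 2.0, 30) == 0.0

    def test_swapping_groups_flips_the_sign(self):
        t1 = summary_ttest(3.1, 0.9, 12, 4.2, 1.1, 14)
        t2 = summary_ttest(4.2, 1.1, 14, 3.1, 0.9, 12)
        assert t1 == pytest.approx(-t2)

    def test_matches_scipy_summary_oracle(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 3, 2)
            n1, n2 = rng.integers(3, 80, 2)
            mine = summary_ttest(m1, s1, int(n1), m2, s2, int(n2))
            ref = sstats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2).statistic
            assert mine == pytest.approx(ref, rel=1e-12)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            summary_ttest(1.0, 0.0, 10, 2.0, 1.0, 10)


class TestGroupContrast:
    def test_matches_pooled_t_without_covariates(self, rng):
        cohort = _cohort()
        values = rng.standard_normal(40)
        res = group_contrast(values, cohort)
        ref = sstats.ttest_ind(values[:20], values[20:], equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_distributions_are_null(self, rng):
        cohort = _cohort(seed=3)
        pvals = [
            group_contrast(np.random.default_rng(i).standard_normal(40), cohort).p_raw
            for i in range(100)
        ]
        assert np.mean(np.array(pvals) < 0.05) < 0.12

    def test_covariate_adjustment_removes_confound(self, rng):
        """A metric driven purely by education is null once education is controlled."""
        cohort = _cohort(seed=5)
        cohort.loc[cohort["group"] == "old", "education"] += 4.0
        values = 0.5 * cohort["education"].to_numpy() + 0.05 * rng.standard_normal(40)
        raw = group_contrast(values, cohort)
        adj = group_contrast(values, cohort, covariates=("education",))
        assert abs(raw.statistic) > 4
        assert abs(adj.statistic) < 3

    def test_constant_metric_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            group_contrast(np.ones(40), _cohort())


class TestMedianSplit:
    def test_study_sized_group_yields_19_per_subgroup(self):
        values = pd.Series(
            np.arange(1, 47, dtype=float), index=[f"s{i:02d}" for i in range(46)]
        )
        split = median_split(values, n_remove_per_side=4)
        assert len(split.low) == len(split.high) == 19
        assert len(split.removed) == 8
        low_vals = sorted(values[s] for s in split.low)
        high_vals = sorted(values[s] for s in split.high)
        removed_vals = sorted(values[s] for s in split.removed)
        assert low_vals == list(range(1, 20))
        assert high_vals == list(range(28, 47))
        assert removed_vals == list(range(20, 28))

    def test_odd_group_rejected_with_guidance(self):
        values = pd.Series(np.arange(45, dtype=float))
        with pytest.raises(ValueError, match="even"):
            median_split(values)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(pd.Series(np.ones(46)))

    def test_ties_resolved_by_value_then_subject_id(self):
        # every tie pattern on 8 subjects with values from {0, 1}
        for pattern in range(1, 255):
            bits = [(pattern >> i) & 1 for i in range(8)]
            if len(set(bits)) == 1:
                continue
            values = pd.Series(
                [float(b) for b in bits], index=[f"s{i}" for i in range(8)]
            )
            split = median_split(values, n_remove_per_side=1)
            order = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
            expected_low = {k for k, _ in order[:3]}
            expected_high = {k for k, _ in order[5:]}
            assert set(split.low) == expected_low
            assert set(split.high) == expected_high

    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    def test_invariant_under_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(7)
        values = pd.Series(rng.standard_normal(20), index=[f"s{i:02d}" for i in range(20)])
        base = median_split(values, 2)
        transformed = median_split(scale * values + shift, 2)
        assert base.assignment == transformed.assignment


class TestCognitionRegression:
    def test_perfect_linear_score(self, rng):
        metric = rng.standard_normal(30)
        res = cognition_regression(metric, 2.0 * metric)
        assert res.statistic == pytest.approx(1.0)
        assert res.estimate == pytest.approx(2.0)

    def test_matches_pingouin_partial_correlation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "metric": rng.standard_normal(40),
                "score": rng.standard_normal(40),
                "edu": rng.standard_normal(40),
            }
        )
        df["score"] += 0.5 * df["metric"] + 0.3 * df["edu"]
        res = cognition_regression(df["metric"], df["score"], df[["edu"]])
        ref = pingouin.partial_corr(df, x="metric", y="score", covar="edu")
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_raw == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_spearman_sees_monotone_nonlinear_link(self, rng):
        metric = rng.uniform(0, 1, 50)
        score = np.exp(3 * metric)  # monotone but curved
        res = cognition_regression(metric, score, method="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_null_type_one_rate(self, rng):
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            r = np.random.default_rng(1000 + i)
            res = cognition_regression(r.standard_normal(30), r.standard_normal(30))
            hits += res.p_raw < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.05)

    def test_constant_score_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cognition_regression(rng.standard_normal(20), np.ones(20))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            cognition_regression(rng.standard_normal(3), rng.standard_normal(3))


def _fdr_oracle(p):
    """Brute-force BH step-up: adjusted_i = min over k >= rank_i of m p_(k) / k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adjusted[idx] = min(1.0, running)
    return adjusted


class TestFdrBh:
    def test_single_p_unchanged(self):
        adj, rej = fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_all_ones_reject_nothing(self):
        adj, rej = fdr_bh([1.0] * 10)
        assert not rej.any()

    def test_uniform_ladder_all_adjust_to_the_top(self):
        adj, rej = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)
        assert rej.all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_equals_bruteforce_stepup(self, pvals):
        adj, _rej = fdr_bh(pvals)
        assert np.allclose(adj, _fdr_oracle(pvals), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


def _mx_with_degrees(k_a, k_b, n=12):
    """Multiplex whose node-0 degrees in the two layers are k_a and k_b."""
    a = np.zeros((n, n), dtype=np.int8)
    for j in range(1, k_a + 1):
        a[0, j] = a[j, 0] = 1
    b = np.zeros((n, n), dtype=np.int8)
    for j in range(1, k_b + 1):
        b[0, j] = b[j, 0] = 1
    return MultiplexNetwork(layers=[a, b], layer_tags=["FA", "PLV"], density=0.2)


class TestLayerContribution:
    def test_identical_layers_show_no_contrast(self):
        nets = [_mx_with_degrees(3, 3) for _ in range(10)]
        results = layer_contribution(nets, region=0)
        assert results[0].statistic == 0.0
        assert results[0].p_fdr == pytest.approx(1.0)

    def test_planted_structural_excess_detected(self, rng):
        nets = [
            _mx_with_degrees(6 + int(rng.integers(0, 3)), 2 + int(rng.integers(0, 2)))
            for _ in range(14)
        ]
        res = layer_contribution(nets, region=0)[0]
        assert res.statistic > 0
        assert res.p_fdr < 0.01

    def test_swapping_layers_flips_the_sign(self, rng):
        nets_a = [_mx_with_degrees(5, 2) for _ in range(8)]
        # add jitter so the paired t is defined
        nets_a[0] = _mx_with_degrees(6, 2)
        nets_b = [
            MultiplexNetwork(
                layers=[mx.layers[1], mx.layers[0]], layer_tags=mx.layer_tags,
                density=mx.density,
            )
            for mx in nets_a
        ]
        t_a = layer_contribution(nets_a, 0)[0].statistic
        t_b = layer_contribution(nets_b, 0)[0].statistic
        assert t_a == pytest.approx(-t_b)

    def test_missing_region_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            layer_contribution([_mx_with_degrees(2, 2)], region="not-a-node")


class TestUnimodalBaseline:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            unimodal_baseline([], pd.DataFrame({"group": []}))

    def test_planted_global_structural_deficit_detected(self, rng):
        from neuroplex import ConnectivityMatrix

        cohort = _cohort(12, 12, seed=9)
        mats = []
        for g in cohort["group"]:
            w = rng.uniform(0.3, 0.8, (20, 20))
            w = np.triu(w, 1)
            if g == "old":
                w *= 0.7  # global white-matter-integrity deficit
            mats.append(
                ConnectivityMatrix(values=w + w.T, modality="FA")
            )
        res = unimodal_baseline(mats, cohort, density=0.3)
        global_row = res[res["effect"] == "global_mean_weight"].iloc[0]
        assert global_row["statistic"] > 5
        assert global_row["p_fdr"] < 1e-6
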