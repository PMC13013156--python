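"""ROC analysis, Youden cut-points, confusion metrics, frequency tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import stroopnorm as sn
from stroopnorm.validation import (YoudenCutpoint, auc, confusion_metrics,
                                   es_frequency_table, percentile_table,
                                   youden_cutpoint)


def brute_force_auc(pos, neg):
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        wins += p > n
        ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_youden(pos, neg):
    pooled = sorted(set(pos) | set(neg))
    cands = [-math.inf] + [(a + b) / 2 for a, b in zip(pooled, pooled[1:])] \
        + [math.inf]
    best = None
    for c in cands:
        sens = sum(p > c for p in pos) / len(pos)
        spec = sum(n <= c for n in neg) / len(neg)
        j = sens + spec - 1
        key = (-j, -spec, c)
        if best is None or key < best[0]:
            best = (key, c, j)
    return best[1], best[2]


class TestAuc:
    def test_perfect_separation(self):
        assert auc([10, 11, 12], [1, 2, 3]) == 1.0

    def test_all_ties(self):
        assert auc([5, 5], [5, 5, 5]) == 0.5

    def test_small_example_by_pair_counting(self):
        # pairs: 6 wins, 0 ties over 9
        assert auc([3, 5, 7], [2, 4, 6]) == pytest.approx(6 / 9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auc([], [1.0])

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=30),
           st.lists(st.integers(0, 20), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_pairs(self, pos, neg):
        assert auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))


class TestYouden:
    def test_perfect_separation_j_one(self):
        rep = youden_cutpoint([10, 11, 12], [1, 2, 3])
        assert rep.youden == pytest.approx(1.0)
        assert 3 < rep.cut_point < 10

    def test_small_example_matches_scan(self):
        rep = youden_cutpoint([3, 5, 7], [2, 4, 6])
        cut, j = brute_force_youden([3, 5, 7], [2, 4, 6])
        assert rep.youden == pytest.approx(1 / 3)
        assert rep.cut_point == cut and rep.youden == pytest.approx(j)

    def test_degenerate_contrast_prefers_specificity(self):
        # pathological group entirely below controls: no cut beats J=0 and
        # the tie-break picks the all-negative classifier (sens 0, spec 1)
        rep = youden_cutpoint([1.0], [2.0, 3.0, 4.0])
        assert rep.youden == pytest.approx(0.0)
        assert rep.sensitivity == 0.0 and rep.specificity == 1.0
        assert math.isnan(rep.ppv)  # nobody classified positive

    @given(st.lists(st.integers(0, 15), min_size=1, max_size=25),
           st.lists(st.integers(0, 15), min_size=1, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_cutpoint_scan(self, pos, neg):
        rep = youden_cutpoint(pos, neg)
        cut, j = brute_force_youden(pos, neg)
        assert rep.cut_point == pytest.approx(cut)
        assert rep.youden == pytest.approx(j)

    def test_auc_field_equals_auc_function(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
        rep = youden_cutpoint(pos, neg)
        assert rep.auc == pytest.approx(auc(pos, neg), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        pos, neg = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        rep = youden_cutpoint(pos, neg)
        rep_t = youden_cutpoint(np.exp(pos), np.exp(neg))
        assert rep_t.auc == pytest.approx(rep.auc, abs=1e-12)
        assert rep_t.youden == pytest.approx(rep.youden, abs=1e-12)
        assert rep_t.sensitivity == pytest.approx(rep.sensitivity)
        assert rep_t.specificity == pytest.approx(rep.specificity)


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(tp=8, fp=1, tn=9, fn=2)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["ppv"] == pytest.approx(8 / 9)
        assert m["npv"] == pytest.approx(9 / 11)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["prevalence"] == pytest.approx(0.5)

    def test_no_false_positives_gives_ppv_one(self):
        assert confusion_metrics(tp=5, fp=0, tn=4, fn=1)["ppv"] == 1.0

    def test_zero_denominator_reported_missing(self):
        m = confusion_metrics(tp=0, fp=0, tn=5, fn=3)
        assert math.isnan(m["ppv"])

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    @settings(max_examples=100, deadline=None)
    def test_accuracy_identity(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = confusion_metrics(tp, fp, tn, fn)
        assert m["accuracy"] == pytest.approx(
            m["prevalence"] * m["sensitivity"]
            + (1 - m["prevalence"]) * m["specificity"], abs=1e-12)


class TestEsFrequencies:
    def test_single_class_group(self):
        df = pd.DataFrame({"T4": [0, 0, 0, 0], "group": ["AD"] * 4})
        tab = es_frequency_table(df, "AD")
        assert tab.loc[tab.es == 0, "T4_n"].item() == 4
        assert tab.loc[tab.es == 0, "T4_pct"].item() == 100.0

    def test_empty_group_all_zero(self):
        df = pd.DataFrame({"T4": [0], "group": ["AD"]})
        tab = es_frequency_table(df, "MCI")
        assert (tab["T4_n"] == 0).all()

    def test_counts_sum_to_nonmissing_n(self, clinical_adjusted,
                                         published_bands):
        adj = clinical_adjusted["AD"]
        es = [sn.assign_es(v, published_bands["T4"])
              for v in adj["adj_t4"].dropna()]
        df = pd.DataFrame({"T4": es, "group": "AD"})
        tab = es_frequency_table(df, "AD")
        assert tab["T4_n"].sum() == len(es)
        assert tab["T4_pct"].sum() == pytest.approx(100.0, abs=0.05)

    def test_configured_ad_deficit_makes_es0_modal(self, clinical_adjusted,
                                                   published_bands):
        adj = clinical_adjusted["AD"]
        es = np.array([sn.assign_es(v, published_bands["T4"])
                       for v in adj["adj_t4"].dropna()])
        counts = [np.sum(es == k) for k in range(5)]
        assert int(np.argmax(counts)) == 0


class TestPercentileTable:
    def test_self_consistency_patients_equal_healthy(self):
        rng = np.random.default_rng(5)
        healthy = rng.normal(size=20_000)
        tab = percentile_table(healthy, {"p": healthy}, percentiles=(25, 75))
        for _, row in tab.iterrows():
            assert row["p_pct_worse"] == pytest.approx(
                100 - row["percentile"], abs=1.0)

    def test_uniformly_worse_patients(self):
        tab = percentile_table([1, 2, 3], {"p": [10, 11]},
                               percentiles=(5, 50, 95))
        assert (tab["p_pct_worse"] == 100.0).all()

    def test_shifted_normal_matches_tail_oracle(self):
        rng = np.random.default_rng(6)
        healthy = rng.normal(0, 1, 100_000)
        patients = rng.normal(1.0, 1.0, 100_000)
        tab = percentile_table(healthy, {"p": patients}, percentiles=(50, 90))
        for _, row in tab.iterrows():
            z = stats.norm.ppf(row["percentile"] / 100)
            expected = 100 * stats.norm.sf(z - 1.0)
            assert row["p_pct_worse"] == pytest.approx(expected, abs=1.0)


class TestCutpointEstimator:
    def test_fit_predict_shape(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        y = np.array([0] * 50 + [1] * 50)
        clf = YoudenCutpoint(score_name="T4").fit(x, y)
        pred = clf.predict(x)
        assert pred.shape == (100,)
        assert clf.report_.auc > 0.8
        assert (pred == (x > clf.cut_point_)).all()

    def test_group_separation_ordering(self, clinical_adjusted):
        h = clinical_adjusted["healthy"]["adj_t4"].dropna()
        a = clinical_adjusted["AD"]["adj_t4"].dropna()
        m = clinical_adjusted["MCI"]["adj_t4"].dropna()
        assert auc(a, h) > auc(m, h) > 0.5
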