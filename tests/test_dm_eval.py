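"""Differential-methylation scoring: ROC AUC, weighting, correlation, composite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, strategies as st

from methbench.dm_eval import (
    delta_correlation,
    dm_composite,
    evaluate_dm,
    fisher_mean_correlation,
    make_differential_table,
    reference_labels_from_truth,
    roc_auc,
    weighted_dm_auc,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_six_site_toy_matches_pair_count(self):
        labels = np.array([1, 0, 1, 0, 1, 0], dtype=bool)
        scores = np.array([0.9, 0.9, 0.7, 0.4, 0.2, 0.3])
        # positives .9,.7,.2 vs negatives .9,.4,.3:
        # .9 -> .5+1+1 = 2.5 ; .7 -> 0+1+1 = 2 ; .2 -> 0 ; total 4.5 of 9
        assert roc_auc(labels, scores) == pytest.approx(4.5 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])

    @given(
        labels=st.lists(st.booleans(), min_size=2, max_size=50),
        data=st.data(),
    )
    def test_matches_all_pairs_oracle(self, labels, data):
        assume(any(labels) and not all(labels))
        scores = data.draw(
            st.lists(
                st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 1.0]),  # force ties
                min_size=len(labels), max_size=len(labels),
            )
        )
        from oracles import all_pairs_auc

        got = roc_auc(labels, scores)
        want = all_pairs_auc(np.array(labels), np.array(scores))
        assert got == pytest.approx(want)

    @given(labels=st.lists(st.booleans(), min_size=2, max_size=30), data=st.data())
    def test_score_negation_complement(self, labels, data):
        assume(any(labels) and not all(labels))
        n = len(labels)
        scores = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n,
                     unique=True)
        )
        a = roc_auc(labels, scores)
        b = roc_auc(labels, [-s for s in scores])
        assert a + b == pytest.approx(1.0)


class TestWeightedAuc:
    @pytest.mark.parametrize(
        "ah,nh,al,nl,expected",
        [
            (0.8, 100, 0.6, 100, 0.7),
            (0.77, 50, None, 0, 0.77),
            (0.9, 300, 0.5, 100, 0.8),
        ],
    )
    def test_weighted_means(self, ah, nh, al, nl, expected):
        assert weighted_dm_auc(ah, nh, al, nl) == pytest.approx(expected)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            weighted_dm_auc(None, 0, None, 0)

    @given(
        ah=st.floats(0, 1), al=st.floats(0, 1),
        nh=st.integers(1, 1000), nl=st.integers(1, 1000),
    )
    def test_between_components(self, ah, al, nh, nl):
        w = weighted_dm_auc(ah, nh, al, nl)
        assert min(ah, al) - 1e-12 <= w <= max(ah, al) + 1e-12


class TestDeltaCorrelation:
    def test_identical_deltas(self):
        d = pd.Series([0.1, -0.2, 0.3, 0.0], index=range(4))
        assert delta_correlation(d, d) == pytest.approx(1.0)

    def test_negated_deltas(self):
        d = pd.Series([0.1, -0.2, 0.3, 0.0], index=range(4))
        assert delta_correlation(d, -d) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        x = pd.Series(rng.normal(size=10))
        y = pd.Series(rng.normal(size=10))
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        want = cov / (x.std(ddof=0) * y.std(ddof=0))
        assert delta_correlation(x, y) == pytest.approx(want)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            delta_correlation(pd.Series([0.1] * 5), pd.Series([0.1, 0.2, 0.3, 0.4, 0.5]))

    def test_fisher_average_is_between(self):
        r = fisher_mean_correlation([0.4, 0.8])
        assert 0.4 < r < 0.8


class TestComposite:
    def test_best_on_both(self):
        m = pd.DataFrame(
            dict(weighted_auc=[0.9, 0.7, 0.6], correlation=[0.8, 0.6, 0.4]),
            index=["a", "b", "c"],
        )
        comp = dm_composite(m)
        assert comp["a"] == 1.0 and comp["c"] == 3.0

    def test_split_best_and_worst(self):
        m = pd.DataFrame(
            dict(weighted_auc=[0.9, 0.7, 0.6], correlation=[0.4, 0.6, 0.8]),
            index=["a", "b", "c"],
        )
        assert dm_composite(m)["a"] == 2.0  # rank 1 and rank 3

    def test_tie_gets_average_rank(self):
        m = pd.DataFrame(
            dict(weighted_auc=[0.9, 0.9, 0.7, 0.6], correlation=[0.9, 0.8, 0.7, 0.6]),
            index=list("abcd"),
        )
        comp = dm_composite(m)
        assert comp["a"] == pytest.approx((1.5 + 1) / 2)
        assert comp["b"] == pytest.approx((1.5 + 2) / 2)


class TestEndToEndScoring:
    def test_unbiased_workflow_beats_noisy_one(self):
        """On synthetic DML data the clean workflow's weighted AUC must be
        high and clearly above a heavily noise-distorted workflow's."""
        from methbench.synthetic_data import (
            ProtocolProfile, WorkflowProfile, generate_truth, simulate_calls,
        )

        truth = generate_truth(50_000, 5000, 0.3, seed=31)
        reference = reference_labels_from_truth(truth)
        protocol = ProtocolProfile("p", mean_depth=30, depth_dispersion=5.0)
        aucs = {}
        for wf in (WorkflowProfile("clean"), WorkflowProfile("noisy", noise_sd=0.3)):
            tumor = simulate_calls(truth, "tumor", protocol, wf, seed=31)
            normal = simulate_calls(truth, "normal", protocol, wf, seed=31)
            table = make_differential_table(tumor, normal)
            aucs[wf.name] = evaluate_dm(table, reference)["weighted_auc"]
        assert aucs["clean"] > 0.9
        assert aucs["clean"] > aucs["noisy"]
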