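"""Ground-truth generation and call simulation behave as declared."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methbench.synthetic_data import (
    ProtocolProfile,
    WorkflowProfile,
    blueprint_like_locus_table,
    generate_gold_standard,
    generate_truth,
    load_scenario,
    bundled_scenario_path,
    simulate_calls,
)


class TestGenerateTruth:
    def test_no_dml_means_identical_conditions(self):
        t = generate_truth(500, 0, 0.3, seed=3)
        np.testing.assert_array_equal(t.df["beta_normal"], t.df["beta_tumor"])
        assert (t.df["dml_label"] == "null").all()

    def test_effect_is_exact_and_signed(self):
        t = generate_truth(2000, 200, 0.3, seed=3)
        delta = t.df["beta_tumor"] - t.df["beta_normal"]
        hyper = t.df["dml_label"] == "hyper"
        hypo = t.df["dml_label"] == "hypo"
        assert np.allclose(delta[hyper], 0.3)
        assert np.allclose(delta[hypo], -0.3)
        assert np.allclose(delta[t.df["dml_label"] == "null"], 0.0)
        assert t.df["beta_tumor"].between(0, 1).all()

    def test_same_seed_is_bit_identical(self):
        a = generate_truth(300, 30, 0.2, seed=11)
        b = generate_truth(300, 30, 0.2, seed=11)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_truth(0, 0, 0.3, seed=1)
        with pytest.raises(ValueError):
            generate_truth(10, 11, 0.3, seed=1)

    def test_beta_distribution_matches_declared_mixture(self):
        """The generated betas follow the documented two-component Beta
        mixture (KS two-sample against an independent draw, alpha 0.001)."""
        t = generate_truth(100_000, 0, 0.3, seed=5)
        rng = np.random.default_rng(123456)
        n = 100_000
        comp = rng.random(n) >= 0.25
        ref = np.where(comp, rng.beta(8.0, 2.0, n), rng.beta(1.5, 15.0, n))
        stat, p = stats.ks_2samp(t.df["beta_normal"].to_numpy(), ref)
        assert p > 0.001


class TestSimulateCalls:
    def test_high_depth_recovers_truth(self):
        """With all distortions off and deep coverage, called betas
        concentrate on the truth (binomial concentration)."""
        t = generate_truth(1000, 0, 0.3, seed=7)
        prot = ProtocolProfile("deep", mean_depth=10_000, depth_dispersion=50.0)
        wf = WorkflowProfile("clean")
        cs = simulate_calls(t, "normal", prot, wf, seed=7)
        cs.validate()
        err = np.abs(cs.df["beta"].to_numpy() - t.df["beta_normal"].to_numpy())
        assert np.mean(err <= 0.02) >= 0.99

    def test_retention_matches_binomial_count(self):
        t = generate_truth(10_000, 0, 0.3, seed=7)
        prot = ProtocolProfile("p", mean_depth=30)
        wf = WorkflowProfile("half", retention=0.5)
        cs = simulate_calls(t, "normal", prot, wf, seed=7)
        expected_sd = np.sqrt(10_000 * 0.25)
        assert abs(len(cs) - 5000) <= 3 * expected_sd

    def test_negative_bias_shifts_called_beta(self):
        t = generate_truth(4000, 0, 0.3, seed=7)
        t.df["beta_normal"] = 1.0  # fully methylated everywhere
        t.df["beta_tumor"] = 1.0
        prot = ProtocolProfile("deep", mean_depth=5000, depth_dispersion=50.0)
        wf = WorkflowProfile("under", bias=-0.1)
        cs = simulate_calls(t, "normal", prot, wf, seed=7)
        assert cs.df["beta"].mean() == pytest.approx(0.9, abs=0.005)

    def test_depth_shared_across_workflows_same_library(self):
        t = generate_truth(500, 0, 0.3, seed=9)
        prot = ProtocolProfile("p", mean_depth=20)
        a = simulate_calls(t, "normal", prot, WorkflowProfile("a"), seed=9)
        b = simulate_calls(t, "normal", prot, WorkflowProfile("b"), seed=9)
        np.testing.assert_array_equal(a.df["depth"], b.df["depth"])

    def test_count_inflation_leaves_beta_intact(self):
        t = generate_truth(2000, 0, 0.3, seed=9)
        prot = ProtocolProfile("p", mean_depth=30)
        base = simulate_calls(t, "normal", prot, WorkflowProfile("x"), seed=9)
        doubled = simulate_calls(
            t, "normal", prot,
            WorkflowProfile("x", double_count=True, double_count_fraction=1.0),
            seed=9,
        )
        covered = base.df["depth"] > 0
        np.testing.assert_allclose(
            doubled.df.loc[covered, "beta"], base.df.loc[covered, "beta"]
        )
        np.testing.assert_array_equal(
            doubled.df.loc[covered, "depth"], 2 * base.df.loc[covered, "depth"]
        )

    def test_all_call_set_invariants_hold(self):
        t = generate_truth(3000, 300, 0.3, seed=13)
        prot = ProtocolProfile("pbat", mean_depth=8, depth_dispersion=1.5, gc_skew=1.5)
        wf = WorkflowProfile("messy", retention=0.8, bias=-0.05, noise_sd=0.2,
                             double_count=True, dedup=False)
        for cond in ("normal", "tumor"):
            cs = simulate_calls(t, cond, prot, wf, seed=13)
            cs.validate()


class TestGoldStandard:
    def test_zero_noise_measurements_equal_truth(self):
        t = generate_truth(2000, 0, 0.3, seed=21)
        loci = generate_gold_standard(t, 10, 4, 0.0, seed=21)
        for loc in loci:
            for v in loc.measurements.values():
                assert v == pytest.approx(loc.true_beta)

    def test_too_few_technologies_rejected(self):
        t = generate_truth(2000, 0, 0.3, seed=21)
        with pytest.raises(ValueError):
            generate_gold_standard(t, 10, 2, 0.05, seed=21)

    def test_seeded_runs_identical(self):
        t = generate_truth(2000, 0, 0.3, seed=21)
        a = generate_gold_standard(t, 10, 5, 0.05, seed=21)
        b = generate_gold_standard(t, 10, 5, 0.05, seed=21)
        assert [l.measurements for l in a] == [l.measurements for l in b]
        assert [l.region_id for l in a] == [l.region_id for l in b]

    def test_loci_avoid_dml_sites(self):
        t = generate_truth(4000, 800, 0.3, seed=21)
        labels = t.df["dml_label"].to_numpy()
        for loc in generate_gold_standard(t, 20, 5, 0.05, seed=21):
            assert (labels[loc.site_index] == "null").all()


def test_blueprint_like_panel_shape():
    table = blueprint_like_locus_table(seed=1)
    counts = table.groupby("region")["beta"].count()
    assert len(counts) == 48
    assert counts["r29"] == 3 and counts["r30"] == 3
    assert (counts.drop(["r29", "r30"]) == 5).all()
    assert table["beta"].between(0, 1).all()


def test_bundled_scenario_parses_and_plans_192_runs():
    sc = load_scenario(bundled_scenario_path())
    assert len(sc.workflows) == 10
    assert len(sc.protocols) == 5
    assert len(sc.samples) == 4
    assert len(sc.planned_runs) == 192
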