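import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import auc_pair_counting, fisher_closed_form_2
from mirpanel.containers import validate_sample_metadata
from mirpanel.meta import (
    combine_pvalues,
    combined_panel_roc,
    delong_variance,
    logistic_roc,
    longitudinal_fold_change,
    meta_rank,
    rank_auc,
    select_panel,
)
from mirpanel.normalize import NormalizedExpression, reference_normalize
from mirpanel.simulate import simulate_treatment_response


class TestCombine:
    @given(st.floats(1e-10, 1.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_single_input_identity(self, p):
        assert combine_pvalues([p]) == pytest.approx(p)

    def test_closed_form_example(self):
        assert combine_pvalues([0.01, 0.02]) == pytest.approx(
            fisher_closed_form_2(0.01, 0.02), rel=1e-10
        )
        assert combine_pvalues([0.01, 0.02]) == pytest.approx(0.00190, abs=2e-5)

    def test_no_evidence_limit(self):
        assert combine_pvalues([1.0, 1.0]) == pytest.approx(1.0)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = combine_pvalues([0.0, 0.5])
        assert 0 <= p < 1e-100

    def test_uniform_null_gives_uniform_combined(self):
        rng = np.random.default_rng(0)
        ps = [
            combine_pvalues(pair)
            for pair in rng.uniform(size=(10_000, 2))
        ]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_monotone_in_inputs(self):
        assert combine_pvalues([0.005, 0.02]) < combine_pvalues([0.01, 0.02])


class TestMetaRank:
    def _tables(self):
        a = pd.DataFrame({"feature": ["x", "y", "z"], "p_raw": [0.01, 0.5, 0.3]})
        b = pd.DataFrame({"feature": ["x", "y", "w"], "p_raw": [0.02, 0.5, 0.1]})
        return a, b

    def test_join_ranks_and_excluded(self):
        a, b = self._tables()
        mr = meta_rank(a, b)
        assert list(mr["feature"]) == ["x", "y"]
        assert list(mr["rank"]) == [1, 2]
        assert set(mr.attrs["excluded"]) == {"z", "w"}
        assert mr["combined_p"].iloc[0] == pytest.approx(
            fisher_closed_form_2(0.01, 0.02), rel=1e-10
        )

    def test_empty_intersection_rejected(self):
        a = pd.DataFrame({"feature": ["x"], "p_raw": [0.1]})
        b = pd.DataFrame({"feature": ["y"], "p_raw": [0.1]})
        with pytest.raises(ValueError):
            meta_rank(a, b)

    def test_select_panel_monotone_in_threshold(self):
        a, b = self._tables()
        mr = meta_rank(a, b)
        assert select_panel(mr, 0.0) == []
        small = select_panel(mr, 0.01)
        large = select_panel(mr, 1.1)
        assert set(small) <= set(large)
        assert large == ["x", "y"]


class TestRoc:
    def test_worked_example(self):
        r = logistic_roc([1, 3, 2, 4], [False, False, True, True])
        assert r.auc == pytest.approx(0.75)

    def test_all_equal_values_uninformative(self):
        r = logistic_roc([2.0] * 8, [True] * 4 + [False] * 4)
        assert r.auc == pytest.approx(0.5)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        lab = rng.uniform(size=20) > 0.4
        a1 = rank_auc(v, lab)
        a2 = rank_auc(v, ~lab)
        assert a1 == pytest.approx(1 - a2)

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.integers(0, 10, size=16).astype(float)  # with ties
            lab = np.concatenate([np.ones(8, bool), np.zeros(8, bool)])
            assert rank_auc(v, lab) == pytest.approx(auc_pair_counting(v, lab))

    def test_perfect_separation_flagged(self):
        r = logistic_roc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert r.auc == pytest.approx(1.0)
        assert r.ci_low == r.ci_high == 1.0
        assert not r.converged

    def test_delong_coverage(self):
        rng = np.random.default_rng(0)
        mu = 1.0
        true_auc = stats.norm.cdf(mu / np.sqrt(2))
        cover = 0
        n_sim = 500
        for _ in range(n_sim):
            scores = np.concatenate(
                [rng.normal(0, 1, 20), rng.normal(mu, 1, 20)]
            )
            labels = np.array([False] * 20 + [True] * 20)
            auc, var = delong_variance(scores, labels)
            se = np.sqrt(var)
            cover += auc - 1.96 * se <= true_auc <= auc + 1.96 * se
        assert cover / n_sim >= 0.90

    def test_single_feature_panel_reduces_to_univariate(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10)])
        labels = np.array([False] * 10 + [True] * 10)
        r1 = logistic_roc(v, labels)
        r2 = combined_panel_roc(pd.DataFrame({"f": v}), labels)
        assert r1.auc == pytest.approx(r2.auc)
        assert r1.ci_low == pytest.approx(r2.ci_low)

    def test_combined_panel_beats_best_single_with_independent_effects(self):
        rng = np.random.default_rng(3)
        wins = 0
        n_trials = 100
        for _ in range(n_trials):
            n = 25
            labels = np.array([False] * n + [True] * n)
            f1 = rng.normal(0, 1, 2 * n) + 1.2 * labels
            f2 = rng.normal(0, 1, 2 * n) + 1.2 * labels
            x = pd.DataFrame({"f1": f1, "f2": f2})
            best_single = max(rank_auc(f1, labels), rank_auc(f2, labels))
            combined = combined_panel_roc(x, labels).auc
            wins += combined >= best_single
        assert wins / n_trials >= 0.90

    def test_perfectly_separating_panel(self):
        x = pd.DataFrame({"f1": [0, 0, 0, 5, 5, 5], "f2": [1, 0, 1, 6, 7, 6]})
        labels = np.array([False] * 3 + [True] * 3)
        assert combined_panel_roc(x, labels).auc == pytest.approx(1.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            combined_panel_roc(pd.DataFrame(index=[0, 1]), np.array([True, False]))


class TestLongitudinal:
    def _profile(self, **kwargs):
        cq, meta, truth = simulate_treatment_response(**kwargs)
        expr = reference_normalize(cq, truth.stable_features)
        return (
            longitudinal_fold_change(expr, meta, truth.panel_features),
            truth,
        )

    def test_baseline_fold_change_exactly_one(self):
        prof, _ = self._profile(seed=0)
        base = prof[prof["timepoint_months"] == 0]
        assert np.allclose(base["fold_change_vs_baseline"], 1.0)

    def test_planted_decline_recovered_monotone(self):
        prof, truth = self._profile(seed=1, decline_log2_per_step=1.0, noise_sd=0.1)
        med = prof.groupby("timepoint_months")["fold_change_vs_baseline"].median()
        assert (med.diff().dropna() < 0).all()

    def test_relapse_turns_profile_upward(self):
        prof, _ = self._profile(
            seed=2,
            decline_log2_per_step=1.0,
            noise_sd=0.1,
            relapse_spec={"A": [11.0]},
        )
        a = prof[prof["patient_id"] == "A"]
        med = a.groupby("timepoint_months")["fold_change_vs_baseline"].median()
        assert med.loc[11.0] > med.loc[4.0]

    def test_zero_decline_stays_near_one(self):
        prof, _ = self._profile(seed=3, decline_log2_per_step=0.0, noise_sd=0.05)
        assert np.abs(np.log2(prof["fold_change_vs_baseline"])).median() < 0.2

    def test_missing_baseline_skipped_with_reason(self):
        cq, meta, truth = simulate_treatment_response(seed=4)
        expr = reference_normalize(cq, truth.stable_features)
        meta2 = meta.copy()
        # drop patient A's baseline sample
        keep = ~((meta2["patient_id"] == "A") & (meta2["timepoint_months"] == 0))
        prof = longitudinal_fold_change(expr, meta2[keep], truth.panel_features)
        assert "A" not in set(prof["patient_id"])
        assert {"patient_id": "A", "reason": "missing_baseline"} in prof.attrs[
            "skipped"
        ]

    def test_unit_effect_gives_fold_change_two(self):
        values = pd.DataFrame(
            {"P_t0": [1.0], "P_t3": [2.0]}, index=["m1"]
        )
        expr = NormalizedExpression(values)
        meta = validate_sample_metadata(
            pd.DataFrame(
                {
                    "sample_id": ["P_t0", "P_t3"],
                    "group": ["disease"] * 2,
                    "biofluid": ["plasma"] * 2,
                    "patient_id": ["P", "P"],
                    "timepoint_months": [0.0, 3.0],
                }
            )
        )
        prof = longitudinal_fold_change(expr, meta, ["m1"])
        at3 = prof[prof["timepoint_months"] == 3.0]
        assert at3["fold_change_vs_baseline"].iloc[0] == pytest.approx(2.0)
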