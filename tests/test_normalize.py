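import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd

from _oracles import normfinder_bruteforce, tmm_factor_bruteforce
from mirpanel.containers import CountMatrix, CqMatrix
from mirpanel.normalize import (
    best_normalizer_pair,
    expression_filter,
    global_mean_normalize,
    normfinder_stability,
    reference_normalize,
    tmm_factors,
    tpm,
    zscore_cluster_pca,
)
from mirpanel.simulate import simulate_qpcr_study


def _cq(values: dict, index) -> CqMatrix:
    return CqMatrix(pd.DataFrame(values, index=index))


class TestGlobalMean:
    def test_two_assay_arithmetic(self):
        m = _cq({"S1": [20.0, 30.0]}, ["A", "B"])
        out = global_mean_normalize(m)
        assert out.values.at["A", "S1"] == 5.0
        assert out.values.at["B", "S1"] == -5.0
        assert out.normalizer_spec["reference_assays"] == ["A", "B"]

    def test_undetected_feature_excluded_from_reference_everywhere(self):
        vals = pd.DataFrame(
            {"S1": [20.0, 30.0, np.nan], "S2": [22.0, 28.0, 25.0]},
            index=["A", "B", "C"],
        )
        out = global_mean_normalize(CqMatrix(vals))
        # C undetected in S1 -> reference set is {A, B} in every sample
        assert out.normalizer_spec["reference_assays"] == ["A", "B"]
        assert out.values.at["A", "S2"] == pytest.approx(25.0 - 22.0)

    def test_single_feature_all_zero(self):
        out = global_mean_normalize(_cq({"S1": [24.0], "S2": [31.0]}, ["A"]))
        assert (out.values.to_numpy() == 0).all()

    def test_reference_mean_zero_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.uniform(20, 32, size=(6, 4)),
            index=list("ABCDEF"),
            columns=["S1", "S2", "S3", "S4"],
        )
        out = global_mean_normalize(CqMatrix(vals))
        assert np.allclose(out.values.mean(axis=0), 0.0)
        shifted = CqMatrix(vals + pd.Series([1.0, -2.0, 0.5, 3.0], index=vals.columns))
        out2 = global_mean_normalize(shifted)
        pd.testing.assert_frame_equal(out.values, out2.values)

    def test_empty_reference_set_errors(self):
        vals = pd.DataFrame({"S1": [20.0, np.nan], "S2": [np.nan, 25.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="reference_normalize"):
            global_mean_normalize(CqMatrix(vals))


class TestReferenceNormalize:
    def test_pair_reference_arithmetic(self):
        m = _cq({"S1": [20.0, 22.0, 19.0]}, ["R1", "R2", "T"])
        out = reference_normalize(m, ["R1", "R2"])
        assert out.values.at["T", "S1"] == pytest.approx(2.0)
        assert out.values.at["R1", "S1"] == pytest.approx(1.0)

    def test_target_equal_to_ref_mean_is_zero(self):
        m = _cq({"S1": [20.0, 22.0, 21.0]}, ["R1", "R2", "T"])
        assert reference_normalize(m, ["R1", "R2"]).values.at["T", "S1"] == 0.0

    def test_errors(self):
        m = _cq({"S1": [20.0, np.nan]}, ["R1", "T"])
        with pytest.raises(ValueError):
            reference_normalize(m, [])
        vals = pd.DataFrame({"S1": [np.nan, 20.0]}, index=["R1", "T"])
        with pytest.raises(ValueError, match="S1"):
            reference_normalize(CqMatrix(vals), ["R1"])


class TestStability:
    def _toy(self, seed=0, n_genes=4, n_per=6):
        rng = np.random.default_rng(seed)
        samples = [f"D{i}" for i in range(n_per)] + [f"H{i}" for i in range(n_per)]
        base = rng.uniform(22, 30, n_genes)
        noise = rng.normal(0, [0.2, 0.5, 0.8, 1.1][:n_genes], (2 * n_per, n_genes)).T
        effect = np.array([0.0, 0.3, -0.5, 1.0][:n_genes])
        vals = base[:, None] + noise
        vals[:, :n_per] += effect[:, None]
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=samples)
        return CqMatrix(df), samples

    def _meta(self, samples, two_group_meta):
        d = [s for s in samples if s.startswith("D")]
        h = [s for s in samples if s.startswith("H")]
        return two_group_meta(d, h)

    def test_constant_gene_ranks_first_with_near_zero_stability(
        self, two_group_meta
    ):
        rng = np.random.default_rng(1)
        samples = [f"D{i}" for i in range(8)] + [f"H{i}" for i in range(8)]
        vals = pd.DataFrame(
            rng.normal(26, 1.5, size=(5, 16)),
            index=[f"g{i}" for i in range(5)],
            columns=samples,
        )
        vals.loc["g0"] = 25.0  # perfectly constant gene
        st = normfinder_stability(CqMatrix(vals), self._meta(samples, two_group_meta))
        assert st["feature"].iloc[0] == "g0"
        assert st["stability"].iloc[0] < 0.25 * st["stability"].iloc[1]

    def test_matches_bruteforce_oracle(self, two_group_meta):
        m, samples = self._toy(seed=3)
        meta = self._meta(samples, two_group_meta)
        st = normfinder_stability(m, meta)
        data = {
            g: {s: float(-m.values.at[g, s] * np.log(2)) for s in samples}
            for g in m.feature_ids
        }
        group_of = {s: ("disease" if s.startswith("D") else "healthy") for s in samples}
        expected = normfinder_bruteforce(data, group_of)
        got = dict(zip(st["feature"], st["stability"]))
        for g, val in expected.items():
            assert got[g] == pytest.approx(val, abs=1e-8)

    def test_sample_order_permutation_invariant(self, two_group_meta):
        m, samples = self._toy(seed=4)
        meta = self._meta(samples, two_group_meta)
        st1 = normfinder_stability(m, meta)
        perm = list(np.random.default_rng(0).permutation(samples))
        st2 = normfinder_stability(CqMatrix(m.values[perm]), meta)
        pd.testing.assert_frame_equal(st1, st2)

    def test_genewise_shift_invariance(self, two_group_meta):
        m, samples = self._toy(seed=5)
        meta = self._meta(samples, two_group_meta)
        st1 = normfinder_stability(m, meta)
        shifted = CqMatrix(m.values.add(pd.Series([3.0, -1.0, 0.0, 5.0], index=m.values.index), axis=0))
        st2 = normfinder_stability(shifted, meta)
        assert np.allclose(st1["stability"], st2["stability"], atol=1e-10)

    def test_sorted_ascending_and_nonnegative(self, two_group_meta):
        m, samples = self._toy(seed=6, n_genes=4)
        st = normfinder_stability(m, self._meta(samples, two_group_meta))
        assert (st["stability"].diff().dropna() >= 0).all()
        assert (st["stability"] >= 0).all()


class TestNormalizerPair:
    def test_anticorrelated_intergroup_pair_beats_singles(self, two_group_meta):
        rng = np.random.default_rng(2)
        samples = [f"D{i}" for i in range(8)] + [f"H{i}" for i in range(8)]
        noise = rng.normal(0, 0.3, size=(3, 16))
        vals = pd.DataFrame(noise + 26.0, index=["a", "b", "c"], columns=samples)
        # a and b move in opposite directions between groups; the pair cancels
        vals.loc["a", vals.columns[:8]] += 1.0
        vals.loc["b", vals.columns[:8]] -= 1.0
        vals.loc["c"] += rng.normal(0, 1.0, 16)
        meta = two_group_meta(samples[:8], samples[8:])
        m = CqMatrix(vals)
        st = normfinder_stability(m, meta)
        pair, stab, beats = best_normalizer_pair(st, m, meta, top_k=3)
        assert set(pair) == {"a", "b"}
        assert stab < st["stability"].min()
        assert beats

    def test_pair_beats_single_on_study_like_data(self, two_group_meta):
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cq, meta, truth = simulate_qpcr_study(n_per_group=8, seed=100 + seed)
            st = normfinder_stability(cq, meta)
            _, stab, beats = best_normalizer_pair(st, cq, meta, top_k=8)
            wins += beats
        assert wins >= 0.9 * n_seeds

    def test_top_k_one_rejected(self, two_group_meta):
        cq, meta, _ = simulate_qpcr_study(n_per_group=4, seed=0)
        st = normfinder_stability(cq, meta)
        with pytest.raises(ValueError, match=">= 2"):
            best_normalizer_pair(st, cq, meta, top_k=1)


class TestCounts:
    def test_tpm_formula_and_invariances(self):
        c = CountMatrix(
            pd.DataFrame({"S1": [5, 0], "S2": [2, 8]}, index=["g1", "g2"]),
            pd.Series({"S1": 10.0, "S2": 10.0}),
        )
        t = tpm(c)
        assert t.at["g1", "S1"] == 500000
        assert t.at["g2", "S1"] == 0
        doubled = CountMatrix(c.counts * 2, c.mapped_totals * 2)
        pd.testing.assert_frame_equal(tpm(doubled), t)
        # totals from column sums -> columns sum to exactly 1e6
        c2 = CountMatrix(pd.DataFrame({"S1": [5, 15], "S2": [2, 8]}, index=["g1", "g2"]))
        assert np.allclose(tpm(c2).sum(axis=0), 1e6)

    def test_expression_filter_inclusive_floor(self):
        t = pd.DataFrame(
            {"S1": [1.0, 5.0, 0.5], "S2": [1.0, 0.9, 2.0]},
            index=["at_floor", "fails_one", "fails_other"],
        )
        assert expression_filter(t, 1.0) == ["at_floor"]
        assert set(expression_filter(t, 0.0)) == set(t.index)

    def test_tmm_identical_and_proportional_columns(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 1000, size=30)
        c = CountMatrix(
            pd.DataFrame({"S1": col, "S2": col}, index=[f"g{i}" for i in range(30)])
        )
        f = tmm_factors(c)
        assert np.allclose(f.tmm_factor, 1.0)
        c2 = CountMatrix(
            pd.DataFrame({"S1": col, "S2": col * 2}, index=[f"g{i}" for i in range(30)])
        )
        assert np.allclose(tmm_factors(c2).tmm_factor, 1.0, atol=1e-12)

    def test_tmm_matches_bruteforce_on_composition_bias(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(5, 500, size=(20, 2))
        counts[:2, 0] = 50_000  # two genes dominate sample 1
        c = CountMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(20)], columns=["S1", "S2"])
        )
        f = tmm_factors(c)
        lib = c.mapped_totals
        arr = c.counts.to_numpy()
        uq = [
            np.quantile(arr[:, j][arr[:, j] > 0], 0.75) / lib.iloc[j] for j in range(2)
        ]
        ref = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
        other = 1 - ref
        raw = tmm_factor_bruteforce(
            arr[:, other], arr[:, ref], lib.iloc[other], lib.iloc[ref]
        )
        expected = np.ones(2)
        expected[other] = raw
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f.tmm_factor.to_numpy(), expected, atol=1e-6)

    def test_tmm_scale_invariance_per_sample(self):
        # M, A, reference choice and trimming are exactly scale invariant;
        # the precision weights are not (1/y - 1/N rescales for the scaled
        # sample only), so the weighted mean moves slightly.
        rng = np.random.default_rng(3)
        counts = rng.integers(500, 20000, size=(25, 3))
        c = CountMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(25)], columns=list("XYZ")))
        f1 = tmm_factors(c)
        scaled = c.counts.copy()
        scaled["Y"] = scaled["Y"] * 3
        c2 = CountMatrix(scaled, c.mapped_totals * pd.Series({"X": 1, "Y": 3, "Z": 1}))
        f2 = tmm_factors(c2)
        assert np.allclose(
            np.log2(f1.tmm_factor), np.log2(f2.tmm_factor), atol=0.05
        )

    def test_tmm_errors(self):
        c = CountMatrix(pd.DataFrame({"S1": [0, 1]}, index=["a", "b"]))
        with pytest.raises(ValueError, match=">= 2 samples"):
            tmm_factors(c)


class TestClusterPCA:
    def test_identical_samples_merge_at_height_zero(self):
        x = pd.DataFrame(
            {"S1": [1.0, 2.0, 3.0], "S2": [1.0, 2.0, 3.0], "S3": [4.0, 0.0, 1.0]},
            index=["f1", "f2", "f3"],
        )
        res = zscore_cluster_pca(x)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_pairwise_euclidean_distances_hand_computed(self):
        x = pd.DataFrame(
            {"S1": [0.0, 0.0], "S2": [3.0, 4.0], "S3": [6.0, 8.0]},
            index=["f1", "f2"],
        )
        d = ssd.pdist(x.T.to_numpy())
        assert np.allclose(sorted(d), [5.0, 5.0, 10.0])
        res = zscore_cluster_pca(x)
        assert res.linkage[0, 2] == pytest.approx(5.0)

    def test_explained_variance_fractions_well_formed(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(10, 6)))
        res = zscore_cluster_pca(x)
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_constant_feature_dropped_under_correlation_distance(self):
        x = pd.DataFrame(
            {
                "S1": [1.0, 5.0, 2.0],
                "S2": [1.0, 6.0, 1.0],
                "S3": [1.0, 2.0, 7.0],
                "S4": [1.0, 9.0, 3.0],
            },
            index=["const", "varies", "varies2"],
        )
        with pytest.warns(UserWarning, match="const"):
            res = zscore_cluster_pca(x, distance="one_minus_pearson")
        assert res.dropped_features == ["const"]
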