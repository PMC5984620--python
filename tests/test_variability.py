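"""Source separation and four-way variability categorization."""

import numpy as np
import pytest

from conftest import block_rank_k, rank1_matrix
from hfovar.synthetic import generate_rate_matrix, make_rate_scenario
from hfovar.variability import (CategorizerParams, CategoryResult,
                                RateVariabilityModel, _consistency_label,
                                _max_pairwise_spearman, _modal_label, classify,
                                classify_once, is_category_d, nmf_decompose,
                                select_k, source_channels)


class TestNmfDecompose:
    def test_rank1_matches_svd_closed_form(self, rng):
        w = rng.random(8) + 0.1
        h = rng.random(40) * 4
        R = np.outer(w, h)
        model = nmf_decompose(R, K=1, seed=0)
        assert model.reconstruction_error < 1e-3
        # independent oracle: leading singular pair (non-negative here)
        U, s, Vt = np.linalg.svd(R)
        oracle = s[0] * np.outer(np.abs(U[:, 0]), np.abs(Vt[0]))
        assert np.allclose(model.W @ model.H, oracle, atol=1e-6 * s[0])

    def test_factors_non_negative(self, rng):
        R = rng.random((6, 25))
        model = nmf_decompose(R, K=3, seed=1)
        assert model.W.min() >= 0 and model.H.min() >= 0

    def test_scaling_convention_holds(self, rng):
        R = rng.random((6, 25)) * 3
        model = nmf_decompose(R, K=2, seed=2)
        mean_eff = model.H.sum(axis=0).mean()
        mean_wh = (model.W @ model.H).mean()
        assert mean_eff == pytest.approx(mean_wh, rel=1e-9)

    def test_matches_sklearn_reference_fit_quality(self, rng):
        """Cross-check against an independent NMF implementation."""
        sklearn_nmf = pytest.importorskip("sklearn.decomposition").NMF
        R = block_rank_k(2, n_ch=8, n_ep=30) + 0.05 * rng.random((8, 30))
        ours = nmf_decompose(R, K=2, seed=3)
        best_ref = np.inf
        for s in range(3):
            ref = sklearn_nmf(n_components=2, init="random", solver="mu",
                              max_iter=500, tol=1e-6, random_state=s)
            Wr = ref.fit_transform(R)
            err = np.linalg.norm(R - Wr @ ref.components_) / np.linalg.norm(R)
            best_ref = min(best_ref, err)
        assert ours.reconstruction_error <= best_ref * 1.5 + 1e-6

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            nmf_decompose(np.zeros((4, 10)), K=1)

    def test_k_above_min_dimension_rejected(self, rng):
        with pytest.raises(ValueError):
            nmf_decompose(rng.random((3, 10)), K=4)

    def test_seed_determinism(self, rng):
        R = rng.random((5, 20))
        m1 = nmf_decompose(R, K=2, seed=9)
        m2 = nmf_decompose(R, K=2, seed=9)
        assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.H, m2.H)


class TestSelectK:
    def test_rank1_terminates_at_one(self, rng):
        model = select_k(block_rank_k(1), seed=0)
        assert model.K == 1

    def test_two_block_matrix_gives_k2(self):
        # channels 0-3 active in epochs 0-49, channels 4-7 in epochs 50-99
        R = block_rank_k(2, n_ch=8, n_ep=100)
        for seed in range(5):
            assert select_k(R, seed=seed).K == 2

    def test_three_block_matrix_gives_k3(self):
        R = block_rank_k(3, n_ch=9, n_ep=60)
        for seed in range(5):
            assert select_k(R, seed=seed).K == 3

    def test_final_model_has_no_redundant_pair(self, rng):
        for seed in range(3):
            mat, _ = generate_rate_matrix(make_rate_scenario("c", seed=seed))
            model = select_k(mat.R, seed=seed)
            if model.K > 1:
                assert _max_pairwise_spearman(model.H) <= 0.30
                assert _max_pairwise_spearman(model.W.T) <= 0.30

    def test_identity_like_three_blocks(self):
        # three fully independent channel/epoch blocks; the stochastic fits
        # recover K=3 in the clear majority of runs and the vote labels it c
        R3 = np.diag([3.0, 4.0, 5.0])
        ks = [select_k(R3, seed=s).K for s in range(10)]
        assert sum(k == 3 for k in ks) >= 6
        assert classify(R3, seed=0).label == "c"


class TestCategoryRules:
    def test_low_rate_everywhere_is_d_without_nmf(self):
        R = np.full((5, 20), 0.3)
        assert is_category_d(R)
        res = classify(R, seed=0)
        assert res.label == "d"
        assert res.votes == ["d"] * 10 and res.K_per_rep == [0] * 10

    def test_alternating_rates_above_mean_is_a(self):
        # single source, H alternating 5 and 7: 50% strictly above mean 6
        h = np.tile([5.0, 7.0], 15)
        label, model = classify_once(rank1_matrix([1.0, 0.6, 0.2], h), seed=0)
        assert model.K == 1
        assert label == "a"

    def test_source_active_in_first_fifth_is_b(self):
        h = np.zeros(30)
        h[:6] = 6.0     # 80% of epochs at zero violates the 5% rule
        label, model = classify_once(rank1_matrix([1.0, 0.6, 0.2], h), seed=0)
        assert model.K == 1
        assert label == "b"

    def test_constant_envelope_classifies_b_documented_edge(self):
        # "greater than the mean" is strict, so a constant row fails it
        assert _consistency_label(np.full(20, 3.0), CategorizerParams()) == "b"

    def test_rule_thresholds_exact(self):
        p = CategorizerParams()
        h = np.array([2.0] * 4 + [8.0] * 6)    # 60% above mean
        assert _consistency_label(h, p) == "a"
        h = np.array([0.0] * 2 + [5.0] * 18)   # 10% zeros > 5%
        assert _consistency_label(h, p) == "b"


class TestVoting:
    def test_tie_goes_to_more_complex_category(self):
        assert _modal_label(["a"] * 5 + ["b"] * 5) == "b"
        assert _modal_label(["b"] * 5 + ["c"] * 5) == "c"

    def test_modal_vote(self):
        assert _modal_label(["c"] * 4 + ["b"] * 3 + ["a"] * 3) == "c"

    def test_category_result_rejects_non_modal_label(self):
        with pytest.raises(ValueError):
            CategoryResult("a", ["b"] * 6 + ["a"] * 4)

    def test_permutation_invariance_of_vote(self, rng):
        for seed in range(5):
            mat, truth = generate_rate_matrix(make_rate_scenario("c", seed=seed))
            base = classify(mat.R, seed=seed).label
            perm_c = rng.permutation(mat.R.shape[0])
            perm_t = rng.permutation(mat.R.shape[1])
            shuffled = mat.R[np.ix_(perm_c, perm_t)]
            assert classify(shuffled, seed=seed).label == base == truth


class TestSourceChannels:
    def test_half_max_threshold(self):
        model = nmf_decompose(np.outer([1.0, 0.9, 0.1], np.ones(10) * 2),
                              K=1, seed=0)
        (chans,) = source_channels(model)
        assert chans == [0, 1]

    def test_one_hot_and_uniform_columns(self):
        from hfovar.variability import SourceModel
        W = np.array([[1.0, 0.5], [0.0, 0.5], [0.0, 0.5]])
        H = np.ones((2, 4))
        model = SourceModel(K=2, W=W, H=H, seed=0, reconstruction_error=0.0)
        assert source_channels(model) == [[0], [0, 1, 2]]

    def test_zero_column_gives_empty_set(self):
        from hfovar.variability import SourceModel
        model = SourceModel(K=1, W=np.zeros((3, 1)), H=np.ones((1, 4)),
                            seed=0, reconstruction_error=0.0)
        assert source_channels(model) == [[]]


class TestModelResultsSurface:
    def test_fit_exposes_label_votes_and_factors(self):
        mat, truth = generate_rate_matrix(make_rate_scenario("c", seed=11))
        res = RateVariabilityModel(mat).fit(seed=11)
        assert res.label == truth
        assert len(res.votes) == 10
        assert res.K >= 2
        assert res.W.shape == (mat.n_channels, res.K)
        assert res.H.shape == (res.K, mat.n_epochs)

    def test_summary_mentions_category_and_sources(self):
        mat, _ = generate_rate_matrix(make_rate_scenario("a", seed=4))
        res = RateVariabilityModel(mat).fit(seed=4)
        text = res.summary()
        assert "category: a" in text
        assert "source 1" in text

    def test_from_dataframe_roundtrip(self):
        import pandas as pd
        df = pd.DataFrame(np.full((3, 12), 0.1),
                          index=["LA1", "LA2", "LB1"])
        res = RateVariabilityModel.from_dataframe(df).fit()
        assert res.label == "d" and res.W is None

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            RateVariabilityModel(np.array([[1.0, -0.1]]))
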