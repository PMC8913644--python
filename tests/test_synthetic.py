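"""Generator tests: latent structure, reliability control, signal control."""

import numpy as np
import pandas as pd
import pytest

import lba
from lba.errors import InvalidParameterError
from lba.synthetic import population_multiple_r


class TestLatents:
    def test_requested_population_correlation_is_recovered(self):
        lat = lba.generate_latents(100_000, rho=0.85, seed=1)
        r = np.corrcoef(lat.hil_latent, lat.swl_latent)[0, 1]
        assert abs(r - 0.85) < 0.01

    def test_perfect_correlation_gives_identical_traits(self):
        lat = lba.generate_latents(1000, rho=1.0, seed=7)
        np.testing.assert_allclose(lat.hil_latent, lat.swl_latent)

    def test_zero_correlation_gives_independent_traits(self):
        lat = lba.generate_latents(1000, rho=0.0, seed=7)
        assert abs(np.corrcoef(lat.hil_latent, lat.swl_latent)[0, 1]) < 0.1

    @pytest.mark.parametrize("rho", [-1.5, 1.01])
    def test_invalid_correlation_rejected(self, rho):
        with pytest.raises(InvalidParameterError):
            lba.generate_latents(100, rho=rho, seed=0)


class TestScaleItems:
    def test_full_loading_gives_identical_items(self):
        lat = lba.generate_latents(500, 0.85, seed=3)
        scale = lba.generate_scale_items(lat.hil_latent, 5, 1.0, (1, 7), seed=4)
        assert (scale.items.nunique(axis=1) == 1).all()

    def test_zero_loading_gives_uncorrelated_items(self):
        lat = lba.generate_latents(5000, 0.85, seed=3)
        scale = lba.generate_scale_items(lat.hil_latent, 5, 0.0, (1, 7), seed=4, discretize=False)
        assert abs(lba.inter_item_mean(scale)) < 0.05

    @pytest.mark.parametrize("target_r", [0.73, 0.76, 0.5])
    def test_inter_item_correlation_matches_squared_loading(self, target_r):
        # closed form: parallel items with loading a have population r = a^2
        lat = lba.generate_latents(5000, 0.85, seed=5)
        scale = lba.generate_scale_items(
            lat.hil_latent, 5, np.sqrt(target_r), (1, 7), seed=6, discretize=False
        )
        assert lba.inter_item_mean(scale) == pytest.approx(target_r, abs=0.03)

    def test_items_respect_scale_range_and_total(self, small_study):
        scale = small_study.items_hil
        vals = scale.values
        assert vals.min() >= 1 and vals.max() <= 7
        np.testing.assert_allclose(scale.total, vals.sum(axis=1))

    def test_empty_latent_rejected(self):
        with pytest.raises(lba.errors.InvalidInputError):
            lba.generate_scale_items(np.array([]), 5, 0.5, (1, 7), seed=0)


class TestEmbeddings:
    def test_full_signal_is_exact_linear_encoding(self):
        lat = lba.generate_latents(200, 0.85, seed=9)
        emb = lba.generate_response_embeddings(lat.hil_latent, dim=8, signal=1.0, seed=10)
        coef, res, *_ = np.linalg.lstsq(
            np.column_stack([emb.values, np.ones(200)]), lat.hil_latent, rcond=None
        )
        pred = np.column_stack([emb.values, np.ones(200)]) @ coef
        assert np.allclose(pred, lat.hil_latent, atol=1e-8)

    def test_multiple_correlation_matches_closed_form(self):
        # oracle: R^2 = A/(1+A), A = sum s w_j^2/(1-s) for the generating covariance
        n, dim, signal = 20_000, 20, 0.5
        lat = lba.generate_latents(n, 0.85, seed=11)
        emb = lba.generate_response_embeddings(lat.hil_latent, dim=dim, signal=signal, seed=12)
        w = np.random.default_rng(12).standard_normal(dim)  # the generator's fixed weights
        expected = population_multiple_r(signal, w)
        X = np.column_stack([emb.values, np.ones(n)])
        coef, *_ = np.linalg.lstsq(X, lat.hil_latent, rcond=None)
        observed = np.corrcoef(X @ coef, lat.hil_latent)[0, 1]
        assert observed == pytest.approx(expected, abs=0.02)

    def test_columns_have_unit_population_variance(self):
        lat = lba.generate_latents(50_000, 0.0, seed=13)
        emb = lba.generate_response_embeddings(lat.hil_latent, dim=5, signal=0.4, seed=14)
        np.testing.assert_allclose(emb.values.std(axis=0), 1.0, atol=0.03)

    def test_invalid_signal_rejected(self):
        lat = lba.generate_latents(10, 0.0, seed=0)
        with pytest.raises(InvalidParameterError):
            lba.generate_response_embeddings(lat.hil_latent, dim=4, signal=1.2, seed=0)


class TestTokenResponses:
    def test_degenerate_vocabulary_repeats_single_token(self):
        lat = lba.generate_latents(20, 0.0, seed=0)
        vocab = lba.Vocabulary(tokens=("peace",))
        resp = lba.generate_token_responses(lat.hil_latent, vocab, 10, seed=1)
        assert all(t == "peace " * 9 + "peace" for t in resp.texts)
        report = lba.diversity_index([t.split() for t in resp.texts])
        assert report.diversity_index == pytest.approx(1.0)

    def test_uniform_untilted_vocabulary_reaches_full_diversity(self):
        lat = lba.generate_latents(2000, 0.0, seed=0)
        vocab = lba.Vocabulary(tokens=tuple("abcdefgh"))
        resp = lba.generate_token_responses(lat.hil_latent, vocab, 10, seed=1)
        report = lba.diversity_index([t.split() for t in resp.texts])
        assert report.diversity_index == pytest.approx(8.0, abs=0.05)

    def test_word_responses_have_exactly_ten_tokens(self, small_study):
        words = small_study.responses.select(format="words")
        assert all(len(t.split()) == 10 for t in words.texts)

    def test_positive_trait_tilts_towards_positive_tokens(self):
        lat = lba.generate_latents(3000, 0.0, seed=2)
        vocab = lba.default_vocab()["hil"]
        resp = lba.generate_token_responses(lat.hil_latent, vocab, 10, seed=3, tilt=1.5)
        positive = {t for t, v in zip(vocab.tokens, vocab.valences) if v > 0}
        frac_pos = np.array([
            sum(tok in positive for tok in text.split()) / 10 for text in resp.texts
        ])
        assert np.corrcoef(frac_pos, lat.hil_latent)[0, 1] > 0.4

    def test_negative_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            lba.Vocabulary(tokens=("a", "b"), weights=(0.5, -0.1))


class TestContextCodedResponses:
    def test_pair_token_frequencies_carry_no_unigram_signal(self):
        lat = lba.generate_latents(50, 0.0, seed=4)
        resp = lba.generate_context_coded_responses(lat.hil_latent, n_pairs=8, seed=5)
        counts = [
            (t.split().count("steady"), t.split().count("shifting")) for t in resp.texts
        ]
        assert set(counts) == {(8, 8)}

    def test_pair_orientation_tracks_the_trait(self):
        lat = lba.generate_latents(2000, 0.0, seed=4)
        resp = lba.generate_context_coded_responses(lat.hil_latent, n_pairs=12, seed=5)
        frac_forward = []
        for text in resp.texts:
            toks = text.split()
            pairs = list(zip(toks[:24:2], toks[1:24:2]))
            frac_forward.append(np.mean([p == ("steady", "shifting") for p in pairs]))
        assert np.corrcoef(frac_forward, lat.hil_latent)[0, 1] > 0.5


class TestStudyBundle:
    def test_identical_config_reproduces_bit_identical_study(self):
        cfg = lba.SyntheticConfig(n_participants=60, seed=21)
        a, b = lba.generate_study(cfg), lba.generate_study(cfg)
        pd.testing.assert_frame_equal(a.responses.frame, b.responses.frame)
        pd.testing.assert_frame_equal(a.items_hil.items, b.items_hil.items)
        for key in a.embeddings:
            np.testing.assert_array_equal(a.embeddings[key].values, b.embeddings[key].values)
        np.testing.assert_array_equal(a.latents.hil_latent, b.latents.hil_latent)

    def test_study_has_study_sized_tables(self):
        study = lba.generate_study(lba.SyntheticConfig(n_participants=608, seed=1))
        assert study.items_hil.n == study.items_swl.n == 608
        assert len(study.responses) == 608 * 4
        assert all(m.n == 608 for m in study.embeddings.values())

    def test_scale_totals_correlate_strongly(self):
        study = lba.generate_study(lba.SyntheticConfig(n_participants=608, seed=2))
        r = np.corrcoef(study.items_hil.total, study.items_swl.total)[0, 1]
        assert r > 0.6

    def test_total_correlation_matches_generating_covariance(self):
        # oracle: corr(T1, T2) = rho * sqrt(rel1 * rel2), Spearman-Brown totals
        cfg = lba.SyntheticConfig(n_participants=5000, seed=3)
        lat = lba.generate_latents(5000, cfg.rho_latent, seed=30)
        loadings = cfg.loadings
        t = {}
        for c, sd in (("hil", 31), ("swl", 32)):
            latent = lat.hil_latent if c == "hil" else lat.swl_latent
            t[c] = lba.generate_scale_items(
                latent, 5, loadings[c], (1, 7), seed=sd, discretize=False
            ).total
        expected = cfg.rho_latent * np.sqrt(
            lba.total_reliability(loadings["hil"], 5) * lba.total_reliability(loadings["swl"], 5)
        )
        observed = np.corrcoef(t["hil"], t["swl"])[0, 1]
        assert observed == pytest.approx(expected, abs=0.03)

    def test_no_leakage_between_item_noise_and_embeddings(self):
        # token responses and embeddings must be conditionally independent of
        # item noise given the latent trait
        n = 5000
        lat = lba.generate_latents(n, 0.85, seed=40)
        loading = 0.7
        scale = lba.generate_scale_items(lat.hil_latent, 5, loading, (1, 7), seed=41,
                                         discretize=False)
        emb = lba.generate_response_embeddings(lat.hil_latent, dim=4, signal=0.5, seed=42)
        mid, spread = 4.0, 1.0
        noise = (scale.values - mid) / spread - loading * lat.hil_latent[:, None]
        for j in range(emb.dim):
            for k in range(scale.k):
                assert abs(np.corrcoef(emb.values[:, j], noise[:, k])[0, 1]) < 0.05

    def test_participant_ordering_is_shared(self, small_study):
        ids = small_study.participant_ids
        assert small_study.items_swl.participant_ids == ids
        for m in small_study.embeddings.values():
            assert list(m.row_ids) == ids
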