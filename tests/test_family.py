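import numpy as np
import pytest

from ardca.family import (ProfileModel, classification_accuracy,
                          estimate_entropy, exact_entropy, generative_report,
                          log_odds_scores, pca_projection, profile_fit,
                          sequence_space_report)
from ardca.fixtures import (FixtureSpec, random_armodel, two_cluster_msa,
                            two_subfamily_msa)
from ardca.model import uniform_model
from ardca.msa import msa_from_strings, toy_alphabet, uniform_weights
from ardca.stats import empirical_frequencies, site_entropies
from ardca.training import TrainingConfig, fit


class TestEntropy:
    def test_uniform_model_entropy_is_L_ln_q(self):
        model = uniform_model(L=3, q=4, alphabet=toy_alphabet(4))
        assert exact_entropy(model) == pytest.approx(3 * np.log(4), abs=1e-10)
        est = estimate_entropy(model, n_samples=4000, seed=1)
        assert abs(est.S_total - 3 * np.log(4)) <= max(3 * est.stderr, 1e-9)

    def test_delta_model_entropy_zero(self):
        model = uniform_model(L=3, q=3, alphabet=toy_alphabet(3))
        model.h[:, 0] = 200.0
        assert exact_entropy(model) == pytest.approx(0.0, abs=1e-8)

    def test_two_site_toy_matches_hand_sum(self):
        # joint over 2x2: P = (0.4, 0.1, 0.2, 0.3) via explicit AR params
        from ardca.model import ARModel
        from ardca.ordering import direct_order
        # P(x1)=(0.5,0.5); P(x2|x1=0)=(0.8,0.2); P(x2|x1=1)=(0.4,0.6)
        h = np.array([np.log([0.5, 0.5]), np.log([0.8, 0.2])])
        J = [np.zeros((0, 2, 2)),
             np.array([[[0.0, np.log(0.4) - np.log(0.8)],
                        [0.0, np.log(0.6) - np.log(0.2)]]])]
        model = ARModel(h=h, J=J, order=direct_order(2),
                        alphabet=toy_alphabet(2))
        p = np.array([0.4, 0.1, 0.2, 0.3])
        expected = -(p * np.log(p)).sum()
        assert exact_entropy(model) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_sampled_entropy_within_3_stderr_of_enumeration(self, seed):
        spec = FixtureSpec(L=5, q=3, seed=seed, field_scale=0.8,
                           coupling_scale=0.5)
        model = random_armodel(spec, shuffle_order=True)
        exact = exact_entropy(model)
        est = estimate_entropy(model, n_samples=10_000, seed=seed + 100)
        assert abs(est.S_total - exact) <= 3 * est.stderr

    def test_profile_closed_form_matches_sampling(self, profile_armodel):
        exact = profile_armodel.entropy()
        est = estimate_entropy(profile_armodel.to_armodel(),
                               n_samples=10_000, seed=7)
        assert abs(est.S_total - exact) <= 3 * est.stderr

    def test_entropy_bounded_by_maximum(self, small_truth):
        est = estimate_entropy(small_truth, n_samples=2000, seed=8)
        assert est.S_total <= small_truth.L * np.log(small_truth.q) + 3 * est.stderr

    def test_enumeration_cap_enforced(self):
        model = uniform_model(L=10, q=21)
        with pytest.raises(ValueError):
            exact_entropy(model)


class TestSequenceSpace:
    def test_published_response_regulator_numbers(self):
        """S/L = 1.4 nats at L = 112, q = 21: ~1.25e68 functional sequences
        out of ~1.23e148, a fraction of ~1e-80."""
        rep = sequence_space_report(1.4, L=112, q=21)
        assert rep.log10_N == pytest.approx(68.10, abs=0.01)
        assert rep.log10_total == pytest.approx(148.09, abs=0.01)
        assert rep.log10_fraction == pytest.approx(-80.0, abs=0.1)
        assert 10 ** (rep.log10_total - 148) == pytest.approx(1.23, abs=0.01)
        assert 10 ** (rep.log10_N - 68) == pytest.approx(1.25, abs=0.02)

    def test_pure_log_arithmetic_no_overflow(self):
        rep = sequence_space_report(2.5, L=10_000, q=21)
        assert np.isfinite(rep.log10_N) and np.isfinite(rep.log10_fraction)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            sequence_space_report(1.0, L=0, q=21)


class TestProfileModel:
    def test_fit_normalizes_with_pseudocount(self):
        msa = msa_from_strings(["ACDE", "ACDF"])
        prof = profile_fit(msa, pseudocount=0.01)
        assert np.allclose(prof.f.sum(axis=1), 1.0, atol=1e-12)
        assert prof.f.min() > 0

    def test_single_sequence_logprob_with_and_without_pseudocount(self):
        msa = msa_from_strings(["AC"])
        strict = profile_fit(msa, pseudocount=0.0)
        assert strict.log_probability(msa.codes[0]) == pytest.approx(0.0)
        other = msa_from_strings(["CC"]).codes[0]
        assert strict.log_probability(other) == -np.inf
        soft = profile_fit(msa, pseudocount=0.01)
        assert np.isfinite(soft.log_probability(other))

    def test_entropy_of_uniform_profile(self):
        prof = ProfileModel(f=np.full((4, 5), 0.2), alphabet=toy_alphabet(5))
        assert prof.entropy() == pytest.approx(4 * np.log(5), abs=1e-12)

    def test_armodel_conversion_preserves_distribution(self, profile_armodel):
        model = profile_armodel.to_armodel()
        rng = np.random.default_rng(9)
        seqs = rng.integers(0, 4, size=(20, 5))
        assert np.allclose(
            model.log_probability_many(seqs),
            profile_armodel.log_probability_many(seqs),
            atol=1e-10,
        )

    def test_sampling_matches_marginals(self, profile_armodel):
        sample = profile_armodel.sample(50_000, seed=10)
        f = empirical_frequencies(sample, pairwise=False).f1
        assert np.abs(f - profile_armodel.f).max() < 0.01


class TestGenerativeReport:
    def test_natural_vs_itself_through_identity(self, small_sample):
        from ardca.stats import compare_statistics
        comp = compare_statistics(small_sample, small_sample,
                                  n_triplets=300, seed=0)
        assert comp.pearson_f1 == 1.0 and comp.pearson_c2 == 1.0

    def test_truth_sample_scores_high(self, small_truth, small_fit,
                                      small_sample):
        model, _ = small_fit
        rep = generative_report(small_sample, model, n_samples=20_000,
                                n_triplets=2000, seed=11)
        assert rep["pearson_f1"] > 0.99
        assert rep["pearson_c2"] > 0.9

    def test_dimension_mismatch_rejected(self, small_truth):
        msa = msa_from_strings(["ACD"])
        with pytest.raises(ValueError):
            generative_report(msa, small_truth, n_samples=10, n_triplets=5)


class TestPcaProjection:
    def test_weighted_mean_projects_to_origin(self):
        spec = FixtureSpec(L=8, q=4, M=300, seed=60)
        msa = two_cluster_msa(spec).msa
        w = uniform_weights(msa)
        coords = pca_projection(msa, w)[0]
        assert np.abs(coords.mean(axis=0)).max() < 1e-9

    def test_loadings_are_orthogonal(self):
        spec = FixtureSpec(L=8, q=4, M=300, seed=61)
        msa = two_cluster_msa(spec).msa
        # orthogonality shows up as uncorrelated projections under the
        # weighted inner product used to build the covariance
        coords = pca_projection(msa, None)[0]
        cross = coords[:, 0] @ coords[:, 1] / len(coords)
        scale = coords.std(axis=0).prod()
        assert abs(cross) < 1e-8 * max(scale, 1)

    def test_pc1_separates_the_two_clusters(self):
        spec = FixtureSpec(L=10, q=4, M=600, seed=62)
        fixture = two_cluster_msa(spec, sharpness=3.0)
        coords = pca_projection(fixture.msa, None)[0]
        pc1 = coords[:, 0]
        m0 = pc1[fixture.labels == 0].mean()
        m1 = pc1[fixture.labels == 1].mean()
        within = max(pc1[fixture.labels == 0].std(),
                     pc1[fixture.labels == 1].std())
        assert abs(m0 - m1) > 5 * within

    def test_profile_samples_concentrate_near_origin(self):
        """Independent-site resampling of a strongly clustered family
        collapses the cluster structure: profile samples sit at less than
        half the mean projected radius of autoregressive samples."""
        spec = FixtureSpec(L=10, q=4, M=600, seed=63)
        fixture = two_cluster_msa(spec, sharpness=4.0)
        model, _ = fit(fixture.msa, TrainingConfig.preset(
            "generative", order="entropic", theta=None))
        ar_sample = model.sample(600, seed=65)
        prof = profile_fit(fixture.msa, pseudocount=0.01)
        prof_sample = prof.sample(600, seed=64)
        _, ar_coords, prof_coords = pca_projection(
            fixture.msa, None, ar_sample, prof_sample)
        r_ar = np.linalg.norm(ar_coords, axis=1).mean()
        r_prof = np.linalg.norm(prof_coords, axis=1).mean()
        assert r_prof < 0.5 * r_ar

    def test_dimension_mismatch_rejected(self):
        a = msa_from_strings(["ACDE"])
        b = msa_from_strings(["ACD"])
        with pytest.raises(ValueError):
            pca_projection(a, None, b)


class TestLogOdds:
    def test_identical_models_score_zero(self, small_truth, small_sample):
        scores = log_odds_scores(small_truth, small_truth, small_sample)
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_own_samples_score_positive_on_average(self):
        spec = FixtureSpec(L=8, q=4, M=0, seed=65, coupling_scale=0.5)
        m1 = random_armodel(spec)
        m2 = random_armodel(FixtureSpec(L=8, q=4, M=0, seed=66,
                                        coupling_scale=0.5))
        s1 = log_odds_scores(m1, m2, m1.sample(1000, seed=67))
        s2 = log_odds_scores(m1, m2, m2.sample(1000, seed=68))
        assert s1.mean() > 0 and s2.mean() < 0

    def test_ar_at_least_as_accurate_as_profile_on_subfamilies(self):
        spec = FixtureSpec(L=10, q=4, M=3000, seed=30, field_scale=0.5,
                           coupling_scale=0.5)
        sf = two_subfamily_msa(spec, n_divergent_sites=3,
                               divergence_scale=1.0, n_held_out=800)
        cfg = TrainingConfig.preset("generative", order="entropic",
                                    theta=None)
        m1, _ = fit(sf.train_1, cfg)
        m2, _ = fit(sf.train_2, cfg)
        p1 = profile_fit(sf.train_1)
        p2 = profile_fit(sf.train_2)
        acc_ar = classification_accuracy(m1, m2, sf.held_out_1, sf.held_out_2)
        acc_prof = classification_accuracy(p1, p2, sf.held_out_1,
                                           sf.held_out_2)
        assert acc_ar >= acc_prof
        assert acc_ar > 0.8

    def test_length_mismatch_rejected(self, small_truth):
        msa = msa_from_strings(["ACD"])
        with pytest.raises(ValueError):
            log_odds_scores(small_truth, small_truth, msa)
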