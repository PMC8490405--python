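import numpy as np
import pytest
from scipy.stats import spearmanr

from ardca.fixtures import FixtureSpec, random_armodel, random_potts_exact
from ardca.landscape import (apc_correction, contact_scores, dms_scan,
                             dms_scan_naive, effective_couplings, epistasis,
                             ppv_curve, zero_sum_gauge)
from ardca.model import ARModel
from ardca.msa import toy_alphabet
from ardca.ordering import direct_order
from ardca.training import TrainingConfig, fit


@pytest.fixture(scope="module")
def coupled_model():
    spec = FixtureSpec(L=6, q=3, seed=50, field_scale=0.5, coupling_scale=0.6)
    return random_armodel(spec, shuffle_order=True)


@pytest.fixture(scope="module")
def reference(coupled_model):
    return coupled_model.sample(1, seed=51).codes[0]


class TestDmsScan:
    def test_wildtype_entries_exactly_zero(self, coupled_model, reference):
        scan = dms_scan(coupled_model, reference)
        L = coupled_model.L
        assert np.all(scan.delta_E[np.arange(L), reference] == 0.0)

    def test_incremental_equals_naive_energy_difference(
        self, coupled_model, reference
    ):
        fast = dms_scan(coupled_model, reference).delta_E
        slow = dms_scan_naive(coupled_model, reference).delta_E
        assert np.abs(fast - slow).max() < 1e-10

    def test_profile_model_gives_log_frequency_ratio(self, profile_armodel):
        model = profile_armodel.to_armodel()
        ref = np.array([0, 1, 2, 3, 0])
        scan = dms_scan(model, ref)
        f = profile_armodel.f
        for i in range(5):
            for b in range(4):
                expected = np.log(f[i, ref[i]]) - np.log(f[i, b])
                assert scan.delta_E[i, b] == pytest.approx(expected, abs=1e-10)

    def test_background_dependence_with_couplings(self, coupled_model):
        """With nonzero couplings some substitution must score differently
        in two different sequence backgrounds."""
        b1 = coupled_model.sample(1, seed=52).codes[0]
        b2 = b1.copy()
        b2[0] = (b2[0] + 1) % coupled_model.q
        s1 = dms_scan(coupled_model, b1).delta_E
        s2 = dms_scan(coupled_model, b2).delta_E
        # compare substitutions at sites away from the background change
        assert np.abs(s1[2:] - s2[2:]).max() > 1e-6

    def test_invalid_reference_rejected(self, coupled_model):
        with pytest.raises(ValueError):
            dms_scan(coupled_model, np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            dms_scan(coupled_model,
                     np.full(coupled_model.L, coupled_model.q, dtype=int))

    def test_long_format_table(self, coupled_model, reference):
        scan = dms_scan(coupled_model, reference)
        df = scan.to_frame(coupled_model.alphabet)
        assert list(df.columns) == ["position", "wt_aa", "mut_aa", "delta_E"]
        assert len(df) == coupled_model.L * coupled_model.q
        assert df["position"].min() == 1   # 1-based positions


class TestEpistasis:
    def test_identity_mutation_gives_zero(self, coupled_model, reference):
        b = (reference[3] + 1) % coupled_model.q
        dd = epistasis(coupled_model, reference, (1, reference[1]), (3, b))
        assert dd == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_the_two_mutations(self, coupled_model, reference):
        m1 = (1, (reference[1] + 1) % 3)
        m2 = (4, (reference[4] + 2) % 3)
        assert epistasis(coupled_model, reference, m1, m2) == pytest.approx(
            epistasis(coupled_model, reference, m2, m1), abs=1e-12
        )

    def test_zero_for_independent_site_model(self, profile_armodel):
        model = profile_armodel.to_armodel()
        ref = np.array([0, 1, 2, 3, 0])
        for (i, j) in [(0, 1), (1, 4), (2, 3)]:
            dd = epistasis(model, ref, (i, (ref[i] + 1) % 4),
                           (j, (ref[j] + 2) % 4))
            assert dd == pytest.approx(0.0, abs=1e-10)

    def test_same_site_rejected(self, coupled_model, reference):
        with pytest.raises(ValueError):
            epistasis(coupled_model, reference, (2, 0), (2, 1))


class TestEffectiveCouplings:
    def test_wildtype_rows_and_columns_zero(self, coupled_model, reference):
        K = effective_couplings(coupled_model, reference)
        for (i, j), block in K.items():
            assert np.allclose(block[reference[i], :], 0.0, atol=1e-10)
            assert np.allclose(block[:, reference[j]], 0.0, atol=1e-10)

    def test_profile_model_gives_all_zero(self, profile_armodel):
        model = profile_armodel.to_armodel()
        ref = np.array([0, 1, 2, 3, 0])
        K = effective_couplings(model, ref)
        assert all(np.abs(block).max() < 1e-10 for block in K.values())

    def test_two_site_model_recovers_coupling_combination(self):
        """On L=2 the local partition functions cancel in the double
        difference, leaving the pure coupling combination."""
        rng = np.random.default_rng(53)
        q = 3
        h = rng.normal(0, 0.5, size=(2, q))
        J = [np.zeros((0, q, q)), rng.normal(0, 0.8, size=(1, q, q))]
        model = ARModel(h=h, J=J, order=direct_order(2),
                        alphabet=toy_alphabet(q))
        ref = np.array([1, 2])
        K = effective_couplings(model, ref)[(0, 1)]
        a1, a2 = ref
        Jb = J[1][0]   # Jb[state_at_site2, state_at_site1]
        for b1 in range(q):
            for b2 in range(q):
                expected = -(Jb[b2, b1] - Jb[b2, a1] - Jb[a2, b1] + Jb[a2, a1])
                assert K[b1, b2] == pytest.approx(expected, abs=1e-10)


class TestContactScores:
    def test_zero_sum_gauge_rows_and_columns(self, coupled_model, reference):
        K = effective_couplings(coupled_model, reference)
        for block in K.values():
            g = zero_sum_gauge(block)
            assert np.abs(g.sum(axis=0)).max() < 1e-10
            assert np.abs(g.sum(axis=1)).max() < 1e-10

    def test_apc_annihilates_rank_one_scores(self):
        u = np.abs(np.random.default_rng(54).normal(1.0, 0.2, size=8))
        F = np.outer(u, u)
        np.fill_diagonal(F, 0.0)
        # rank-1 separable scores: APC removes the product structure up to
        # the small distortion from excluding the diagonal in the means
        apc = apc_correction(F)
        assert np.abs(apc).max() < 0.1 * F.max()

    def test_symmetry_and_zero_diagonal(self, coupled_model, reference):
        K = effective_couplings(coupled_model, reference)
        scores = contact_scores(K, coupled_model.L, min_sep=1,
                                exclude_gap=False)
        assert np.allclose(scores.F, scores.F.T)
        assert np.all(np.diag(scores.F_apc) == 0)
        assert np.all(scores.F >= 0)

    def test_min_sep_masks_ranked_pairs(self, coupled_model, reference):
        K = effective_couplings(coupled_model, reference)
        scores = contact_scores(K, coupled_model.L, min_sep=3,
                                exclude_gap=False)
        assert all(j - i >= 3 for i, j, _ in scores.ranked_pairs())


@pytest.fixture(scope="module")
def potts_run():
    spec = FixtureSpec(L=10, q=3, M=8000, seed=55, field_scale=0.3,
                       coupling_scale=1.0)
    pf = random_potts_exact(spec, n_coupled_pairs=5, min_pair_sep=2,
                            cap=3**10)
    cfg = TrainingConfig.preset("effects_contacts", order="entropic",
                                theta=None)
    model, _ = fit(pf.msa, cfg)
    return pf, model


class TestContactRecovery:
    def test_top_pairs_are_true_contacts(self, potts_run):
        pf, model = potts_run
        K = effective_couplings(model, pf.msa.codes[0])
        scores = contact_scores(K, model.L, min_sep=2, exclude_gap=False)
        top = {(i, j) for i, j, _ in scores.ranked_pairs()[:5]}
        assert top == pf.true_pairs

    def test_ranking_robust_to_reference_choice(self, potts_run):
        pf, model = potts_run
        iu = np.triu_indices(model.L, k=2)
        maps = []
        for row in (0, 1):
            K = effective_couplings(model, pf.msa.codes[row])
            sc = contact_scores(K, model.L, min_sep=2, exclude_gap=False)
            maps.append(sc.F_apc[iu])
        assert spearmanr(maps[0], maps[1]).statistic > 0.9


class TestPpvCurve:
    def _scores(self, L, values):
        F = np.zeros((L, L))
        K = {}
        for (i, j), v in values.items():
            F[i, j] = F[j, i] = v
            K[(i, j)] = np.zeros((2, 2))
        from ardca.landscape import ContactScores
        return ContactScores(K=K, F=F, F_apc=F, min_sep=1)

    def test_all_true_gives_unit_ppv(self):
        scores = self._scores(4, {(0, 1): 3.0, (0, 2): 2.0, (1, 3): 1.0})
        curve = ppv_curve(scores, {(0, 1), (0, 2), (1, 3)}, min_sep=1)
        assert all(p == 1.0 for _, p in curve[:3])

    def test_none_true_gives_zero_ppv(self):
        scores = self._scores(4, {(0, 1): 3.0, (0, 2): 2.0})
        curve = ppv_curve(scores, set(), min_sep=1)
        assert all(p == 0.0 for _, p in curve)

    def test_three_of_four(self):
        scores = self._scores(
            5, {(0, 1): 4.0, (0, 2): 3.0, (1, 3): 2.0, (2, 4): 1.0}
        )
        curve = ppv_curve(scores, {(0, 1), (0, 2), (1, 3)}, min_sep=1)
        assert curve[3] == (4, 0.75)

    def test_accepts_boolean_matrix(self):
        scores = self._scores(4, {(0, 1): 1.0})
        truth = np.zeros((4, 4), dtype=bool)
        truth[0, 1] = truth[1, 0] = True
        assert ppv_curve(scores, truth, min_sep=1)[0] == (1, 1.0)
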