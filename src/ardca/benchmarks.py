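"""Reproducible end-to-end self-checks of the whole pipeline.

Each function runs one complete experiment on synthetic ground truth —
generate data from a known model, run the method under test, measure the
result — and returns plain numbers.  They power both the test suite and the
standalone reproduction script; everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .family import (classification_accuracy, estimate_entropy, exact_entropy,
                     profile_fit, sequence_space_report)
from .fixtures import FixtureSpec, random_armodel, random_potts_exact, two_subfamily_msa
from .landscape import (contact_scores, dms_scan, dms_scan_naive,
                        effective_couplings, epistasis)
from .model import enumerate_sequences
from .msa import EncodedMSA, toy_alphabet, uniform_weights
from .ordering import direct_order
from .training import (TrainingConfig, _prefix_onehot, _site_objective, fit,
                       fit_site)


def sequence_space_numbers(S_per_site: float = 1.4, L: int = 112,
                           q: int = 21) -> dict:
    """Sequence-space arithmetic at the response-regulator scale.

    An entropy density of 1.4 nats/site over L = 112 sites and q = 21 states
    gives the effective family size, the total q^L, and their ratio, all in
    exact log10 arithmetic.
    """
    rep = sequence_space_report(S_per_site, L, q)
    return {
        "log10_total_sequences": rep.log10_total,
        "log10_family_size": rep.log10_N,
        "log10_family_fraction": rep.log10_fraction,
    }


def normalization_error(seed: int, n_models: int = 20) -> float:
    """Worst |sum_x P(x) - 1| over random small models, by enumeration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for t in range(n_models):
        L = int(rng.integers(3, 6))          # q^L <= 4^5 = 1024 <= 4096
        q = int(rng.integers(2, 5))
        spec = FixtureSpec(L=L, q=q, seed=int(rng.integers(2**31)),
                           field_scale=1.0, coupling_scale=0.8)
        model = random_armodel(spec, shuffle_order=bool(t % 2))
        total = np.exp(model.log_probability_many(
            enumerate_sequences(L, q))).sum()
        worst = max(worst, abs(total - 1.0))
    return worst


def gradient_max_rel_error(seed: int, eps: float = 1e-5) -> float:
    """Analytic site gradient vs central finite differences (L=4,q=3,M=20)."""
    rng = np.random.default_rng(seed)
    q, L, M, k = 3, 4, 20, 3
    codes = rng.integers(0, q, size=(M, L))
    X = _prefix_onehot(codes[:, :k], q)
    T = _prefix_onehot(codes[:, k][:, None], q)
    w = np.ones(M)
    x = rng.normal(0, 0.5, size=q + k * q * q)
    args = (X, T, w, float(M), q, k, 1e-4, 1e-3)
    _, grad = _site_objective(x, *args)
    worst = 0.0
    for idx in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fd = (_site_objective(xp, *args)[0]
              - _site_objective(xm, *args)[0]) / (2 * eps)
        worst = max(worst, abs(grad[idx] - fd) / max(abs(fd), 1e-8))
    return worst


def moment_residual(seed: int, grad_tol: float = 1e-7) -> float:
    """Max |f - <P>_D| over fields and couplings at the lambda=0 optimum."""
    rng = np.random.default_rng(seed)
    q, L, M, k = 3, 4, 20, 3
    codes = rng.integers(0, q, size=(M, L))
    msa = EncodedMSA(codes=codes, ids=[str(i) for i in range(M)],
                     alphabet=toy_alphabet(q))
    cfg = TrainingConfig(lambda_J=0.0, lambda_h=0.0, grad_tol=grad_tol,
                         order=direct_order(L), theta=None)
    h, J, _ = fit_site(k, msa, uniform_weights(msa), cfg)
    logits = h + sum(J[j][:, codes[:, j]].T for j in range(k))
    P = np.exp(logits - logits.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    f1 = np.bincount(codes[:, k], minlength=q) / M
    worst = np.abs(f1 - P.mean(axis=0)).max()
    for j in range(k):
        for b in range(q):
            sel = codes[:, j] == b
            f2 = np.bincount(codes[sel, k], minlength=q) / M
            worst = max(worst, np.abs(f2 - P[sel].sum(axis=0) / M).max())
    return float(worst)


def recovery_mean_tv(seed: int, M: int = 50_000, n_prefixes: int = 100) -> float:
    """Mean total-variation distance of fitted vs true conditionals.

    Ground truth: L=8, q=4 autoregressive model with all pairs coupled;
    fit on M i.i.d. samples with the generative-preset regularization and
    the truth's site order, then compare conditional distributions on
    random prefixes drawn from the truth.
    """
    spec = FixtureSpec(L=8, q=4, seed=seed, field_scale=1.0,
                       coupling_scale=0.35)
    truth = random_armodel(spec, shuffle_order=True)
    data = truth.sample(M, seed=seed + 1)
    cfg = TrainingConfig.preset("generative", order=truth.order, theta=None)
    model, _ = fit(data, cfg)
    rng = np.random.default_rng(seed + 2)
    prefixes = truth.sample(n_prefixes, seed=seed + 3).codes
    perm = list(truth.order.perm)
    tvs = []
    for t in range(n_prefixes):
        k = int(rng.integers(0, truth.L))
        pre = prefixes[t][perm][:k]
        tvs.append(0.5 * np.abs(
            truth.conditional_distribution(k, pre)
            - model.conditional_distribution(k, pre)
        ).sum())
    return float(np.mean(tvs))


def entropy_agreement(seed: int, n_models: int = 10,
                      n_samples: int = 10_000) -> dict:
    """Sampled vs enumerated entropy on random small models, in stderr units.

    Also checks the profile closed form sum_i s_i against sampling on the
    equivalent independent-site autoregressive model.
    """
    rng = np.random.default_rng(seed)
    worst_z = 0.0
    for t in range(n_models):
        spec = FixtureSpec(L=5, q=3, seed=int(rng.integers(2**31)),
                           field_scale=0.8, coupling_scale=0.5)
        model = random_armodel(spec, shuffle_order=bool(t % 2))
        exact = exact_entropy(model)
        est = estimate_entropy(model, n_samples, seed=int(rng.integers(2**31)))
        worst_z = max(worst_z, abs(est.S_total - exact) / est.stderr)
    # profile closed form
    from .family import ProfileModel
    f = np.random.default_rng(seed + 7).dirichlet(np.ones(4) * 2, size=6)
    prof = ProfileModel(f=f, alphabet=toy_alphabet(4))
    est = estimate_entropy(prof.to_armodel(), n_samples, seed=seed + 8)
    prof_z = abs(est.S_total - prof.entropy()) / est.stderr
    return {"max_z": float(worst_z), "profile_z": float(prof_z)}


def contact_recovery(seed: int, M: int = 20_000) -> dict:
    """Contact prediction on the exactly-sampled Potts fixture.

    L=12, q=4, six coupled pairs at separation >= 2; returns the fraction of
    the top-6 APC-ranked pairs that are true couplings, and the Spearman
    correlation of score maps from two different reference sequences.
    """
    spec = FixtureSpec(L=12, q=4, M=M, seed=seed, field_scale=0.3,
                       coupling_scale=1.0)
    pf = random_potts_exact(spec, n_coupled_pairs=6, min_pair_sep=2,
                            cap=4**12)
    cfg = TrainingConfig.preset("effects_contacts", order="entropic",
                                theta=None)
    model, _ = fit(pf.msa, cfg)
    maps = []
    tops = []
    for row in (0, 1):
        K = effective_couplings(model, pf.msa.codes[row])
        sc = contact_scores(K, model.L, min_sep=2, exclude_gap=False)
        maps.append(sc.F_apc[np.triu_indices(model.L, k=2)])
        tops.append({(i, j) for i, j, _ in sc.ranked_pairs()[:6]})
    top6_fraction = len(tops[0] & pf.true_pairs) / 6
    rho = float(spearmanr(maps[0], maps[1]).statistic)
    return {"top6_true_fraction": top6_fraction, "reference_spearman": rho}


def dms_identities(seed: int) -> dict:
    """Exact identities of the mutational-effect machinery.

    Returns the worst deviations from: zero wildtype entries; agreement of
    incremental and naive scans; the profile-model log-frequency closed
    form; epistasis symmetry; zero epistasis under independence.
    """
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(L=6, q=3, seed=seed, field_scale=0.5,
                       coupling_scale=0.6)
    model = random_armodel(spec, shuffle_order=True)
    ref = model.sample(1, seed=seed + 1).codes[0]
    scan = dms_scan(model, ref)
    wt_dev = np.abs(scan.delta_E[np.arange(model.L), ref]).max()
    inc_dev = np.abs(scan.delta_E - dms_scan_naive(model, ref).delta_E).max()

    from .family import ProfileModel
    f = rng.dirichlet(np.ones(3) * 2, size=6)
    prof = ProfileModel(f=f, alphabet=toy_alphabet(3))
    pref = rng.integers(0, 3, size=6)
    pscan = dms_scan(prof.to_armodel(), pref)
    logf = np.log(f)
    expected = logf[np.arange(6), pref][:, None] - logf
    prof_dev = np.abs(pscan.delta_E - expected).max()

    m1 = (0, int((ref[0] + 1) % 3))
    m2 = (4, int((ref[4] + 2) % 3))
    sym_dev = abs(epistasis(model, ref, m1, m2)
                  - epistasis(model, ref, m2, m1))
    indep_dev = max(
        abs(epistasis(prof.to_armodel(), pref,
                      (i, int((pref[i] + 1) % 3)),
                      (j, int((pref[j] + 1) % 3))))
        for i, j in [(0, 3), (1, 5), (2, 4)]
    )
    return {
        "wildtype_deviation": float(wt_dev),
        "incremental_vs_naive": float(inc_dev),
        "profile_closed_form_deviation": float(prof_dev),
        "epistasis_symmetry_deviation": float(sym_dev),
        "independence_epistasis": float(indep_dev),
    }


def subfamily_accuracies(seed: int, M: int = 3000,
                         n_held_out: int = 1000) -> dict:
    """Held-out subfamily assignment accuracy, arDCA vs profile log-odds."""
    spec = FixtureSpec(L=10, q=4, M=M, seed=seed, field_scale=0.5,
                       coupling_scale=0.5)
    sf = two_subfamily_msa(spec, n_divergent_sites=3, divergence_scale=1.0,
                           n_held_out=n_held_out)
    cfg = TrainingConfig.preset("generative", order="entropic", theta=None)
    m1, _ = fit(sf.train_1, cfg)
    m2, _ = fit(sf.train_2, cfg)
    p1 = profile_fit(sf.train_1)
    p2 = profile_fit(sf.train_2)
    return {
        "ardca_accuracy": classification_accuracy(
            m1, m2, sf.held_out_1, sf.held_out_2),
        "profile_accuracy": classification_accuracy(
            p1, p2, sf.held_out_1, sf.held_out_2),
    }
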