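"""Per-site maximum-likelihood inference of the autoregressive model.

Each model position k owns its parameters (h_k, J_k.) and appears in exactly
one conditional, so the weighted log-likelihood decomposes into L independent
soft-max (multinomial logistic) regressions: position k is regressed on the
one-hot encoding of the k preceding positions in model order.  The objective
per site, maximized, is

    (1/Meff) sum_m w_m log P(a_k^m | prefix^m)  -  lambda_h ||h_k||^2
                                                -  lambda_J ||J_k||^2

whose gradient is exact (an explicit data average, no sampling):

    d/dh_k(a)    :  f_k(a)    - < P(a_k=a | prefix) >_D    - 2 lambda_h h
    d/dJ_kj(a,b) :  f_kj(a,b) - < P(a_k=a | prefix) [a_j=b] >_D - 2 lambda_J J

Optimization uses the low-storage BFGS method (L-BFGS); at the optimum with
lambda = 0 the moment conditions f = <P>_D hold to the gradient tolerance.
The first position in the order has no predecessors and with lambda_h = 0 its
fields have the closed form h_1(a) = log f_1(a) + const.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize

from .model import ARModel
from .msa import EncodedMSA, SequenceWeights, compute_weights, uniform_weights
from .ordering import (SiteOrder, apply_order, direct_order, entropic_order,
                       random_order)
from .stats import empirical_frequencies, site_entropies

PRESETS = {
    # generative use: small regularization reproduces statistics best
    "generative": {"lambda_J": 1e-4, "lambda_h": 1e-6},
    # mutational effects / contacts: stronger shrinkage of couplings
    "effects_contacts": {"lambda_J": 1e-2, "lambda_h": 1e-4},
}

_FREQ_FLOOR = 1e-12


@dataclass
class TrainingConfig:
    """Hyperparameters of the per-site regularized fits.

    lambda_J, lambda_h : L2 strengths applied as lambda * sum(param^2)
        (no 1/2 factor) on the Meff-normalized mean log-likelihood.
    order : "entropic" | "direct" | "random" | SiteOrder instance.
    theta : reweighting identity threshold; None disables reweighting
        (unit weights), appropriate for i.i.d. samples.
    """

    lambda_J: float = 1e-4
    lambda_h: float = 1e-6
    max_iter: int = 500
    grad_tol: float = 1e-5
    order: object = "entropic"
    theta: float | None = 0.8
    pseudocount: float = 0.0
    seed: int = 0  # only used for order="random"

    def __post_init__(self) -> None:
        if self.lambda_J < 0 or self.lambda_h < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.grad_tol <= 0:
            raise ValueError("grad_tol must be positive")

    @classmethod
    def preset(cls, name: str, **overrides) -> "TrainingConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **overrides})


@dataclass
class SiteReport:
    position: int          # model position
    converged: bool
    grad_inf_norm: float
    n_iterations: int
    mean_loglik: float     # weighted mean conditional log-likelihood


@dataclass
class FitReport:
    sites: list[SiteReport] = dc_field(default_factory=list)
    mean_loglik: float = 0.0   # total weighted mean log-likelihood (nats/seq)
    Meff: float = 0.0
    wall_time_s: float = 0.0

    @property
    def all_converged(self) -> bool:
        return all(s.converged for s in self.sites)


def _prefix_onehot(prefix: np.ndarray, q: int) -> np.ndarray:
    """One-hot encode an (M, k) prefix matrix as (M, k*q) float64."""
    M, k = prefix.shape
    X = np.zeros((M, k * q), dtype=np.float64)
    if k:
        X[np.arange(M)[:, None], np.arange(k) * q + prefix] = 1.0
    return X


def _site_objective(x, X, target_onehot, w, Meff, q, k, lam_h, lam_J):
    """Negative regularized mean log-likelihood and its exact gradient."""
    h = x[:q]
    Jmat = x[q:].reshape(k * q, q)       # Jmat[j*q+b, a] = J_kj(a, b)
    logits = X @ Jmat + h                # (M, q)
    m = logits.max(axis=1, keepdims=True)
    ez = np.exp(logits - m)
    z = ez.sum(axis=1)
    logz = np.log(z) + m[:, 0]
    ll = (w @ ((logits * target_onehot).sum(axis=1) - logz)) / Meff
    obj = -ll + lam_h * h @ h + lam_J * (Jmat * Jmat).sum()

    P = ez / z[:, None]
    R = (P - target_onehot) * (w / Meff)[:, None]   # <P> - f, weighted
    g_h = R.sum(axis=0) + 2 * lam_h * h
    g_J = X.T @ R + 2 * lam_J * Jmat
    return obj, np.concatenate([g_h, g_J.ravel()])


def _run_lbfgs(x0, args, grad_tol, max_iter):
    res = minimize(
        _site_objective, x0, args=args, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                 "gtol": grad_tol, "ftol": 1e-16},
    )
    grad_norm = float(np.abs(res.jac).max())
    return res.x, grad_norm, int(res.nit), bool(grad_norm <= grad_tol * 10)


def fit_site(
    k: int,
    permuted_msa: EncodedMSA,
    weights: SequenceWeights,
    config: TrainingConfig,
) -> tuple[np.ndarray, np.ndarray, SiteReport]:
    """Fit fields and couplings of model position k >= 1.

    Returns (h_k of shape (q,), J_k of shape (k, q, q), report), with
    J_k[j, a, b] the coupling from predecessor j onto state a at k.
    """
    if k < 1:
        raise ValueError("position 0 is handled by fit_first_site")
    q = permuted_msa.q
    prefix = permuted_msa.codes[:, :k]
    target = permuted_msa.codes[:, k]
    X = _prefix_onehot(prefix, q)
    T = _prefix_onehot(target[:, None], q)
    w, Meff = weights.w, weights.Meff

    x0 = np.zeros(q + k * q * q)
    args = (X, T, w, Meff, q, k, config.lambda_h, config.lambda_J)
    x, gnorm, nit, converged = _run_lbfgs(x0, args, config.grad_tol, config.max_iter)
    obj, _ = _site_objective(x, *args)
    h = x[:q]
    Jmat = x[q:].reshape(k * q, q)
    J = Jmat.reshape(k, q, q).transpose(0, 2, 1)   # -> J[j, a, b]
    ll = -(obj - config.lambda_h * h @ h - config.lambda_J * (Jmat * Jmat).sum())
    if not np.isfinite(obj):
        raise FloatingPointError(f"non-finite objective at site {k}")
    report = SiteReport(position=k, converged=converged, grad_inf_norm=gnorm,
                        n_iterations=nit, mean_loglik=float(ll))
    return h, J, report


def fit_first_site(
    permuted_msa: EncodedMSA,
    weights: SequenceWeights,
    config: TrainingConfig,
) -> tuple[np.ndarray, SiteReport]:
    """Fields of the unconditioned first position.

    With lambda_h = 0 the maximum-likelihood solution is closed form,
    h(a) = log f(a) + const (frequencies floored at 1e-12); otherwise the
    same L-BFGS machinery runs restricted to fields.
    """
    q = permuted_msa.q
    target = permuted_msa.codes[:, 0]
    w, Meff = weights.w, weights.Meff
    f = np.zeros(q)
    np.add.at(f, target, w)
    f /= Meff
    if config.lambda_h == 0:
        h = np.log(np.maximum(f, _FREQ_FLOOR))
        h -= h.mean()
        ll = float(f @ np.log(np.maximum(f, _FREQ_FLOOR)))
        return h, SiteReport(position=0, converged=True, grad_inf_norm=0.0,
                             n_iterations=0, mean_loglik=ll)
    X = np.zeros((permuted_msa.M, 0))
    T = _prefix_onehot(target[:, None], q)
    x0 = np.zeros(q)
    args = (X, T, w, Meff, q, 0, config.lambda_h, config.lambda_J)
    x, gnorm, nit, converged = _run_lbfgs(x0, args, config.grad_tol, config.max_iter)
    obj, _ = _site_objective(x, *args)
    h = x[:q]
    ll = -(obj - config.lambda_h * h @ h)
    return h, SiteReport(position=0, converged=converged, grad_inf_norm=gnorm,
                         n_iterations=nit, mean_loglik=float(ll))


def resolve_order(msa: EncodedMSA, weights: SequenceWeights,
                  order) -> SiteOrder:
    """Turn an order request (label string or SiteOrder) into a SiteOrder.

    The entropic order uses reweighted, pseudocount-free column entropies.
    """
    if isinstance(order, SiteOrder):
        if order.L != msa.L:
            raise ValueError("supplied order length does not match alignment")
        return order
    if order == "direct":
        return direct_order(msa.L)
    if order == "entropic":
        f = empirical_frequencies(msa, weights, pseudocount=0.0, pairwise=False)
        return entropic_order(site_entropies(f.f1))
    raise ValueError(f"unknown order {order!r}")


def fit(
    msa: EncodedMSA,
    config: TrainingConfig | None = None,
    weights: SequenceWeights | None = None,
) -> tuple[ARModel, FitReport]:
    """Train an autoregressive model on an encoded alignment.

    Computes sequence weights (unless supplied or disabled via
    ``config.theta=None``), resolves the site order, then solves the L
    independent per-site regressions sequentially (they share no parameters,
    so the result equals any concurrent schedule).  Deterministic: refitting
    with identical inputs yields bit-identical parameters.
    """
    t0 = time.perf_counter()
    config = config or TrainingConfig()
    if weights is None:
        weights = (compute_weights(msa, config.theta)
                   if config.theta is not None else uniform_weights(msa))
    if isinstance(config.order, str) and config.order == "random":
        order = random_order(msa.L, config.seed)
    else:
        order = resolve_order(msa, weights, config.order)
    permuted = apply_order(msa, order)

    q = msa.q
    h = np.zeros((msa.L, q))
    J: list[np.ndarray] = [np.zeros((0, q, q))]
    report = FitReport(Meff=weights.Meff)
    h0, rep0 = fit_first_site(permuted, weights, config)
    h[0] = h0
    report.sites.append(rep0)
    for k in range(1, msa.L):
        hk, Jk, rep = fit_site(k, permuted, weights, config)
        h[k] = hk
        J.append(Jk)
        report.sites.append(rep)
    report.mean_loglik = float(sum(s.mean_loglik for s in report.sites))
    report.wall_time_s = time.perf_counter() - t0

    meta = {
        "lambda_J": config.lambda_J,
        "lambda_h": config.lambda_h,
        "Meff": weights.Meff,
        "theta": config.theta,
        "order_label": order.label,
        "mean_loglik": report.mean_loglik,
        "loglik_normalization": "mean (1/Meff)",
    }
    model = ARModel(h=h, J=J, order=order, alphabet=msa.alphabet, meta=meta)
    return model, report
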