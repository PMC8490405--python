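# Methods

## Model

An aligned family of M sequences of length L over q = 21 states (20 amino
acids + gap) is modeled autoregressively: after permuting columns into a
chosen *site order*, the joint probability is the product of soft-max
conditionals

    P(a_k | a_{k-1}, ..., a_1) ∝ exp( h_k(a_k) + Σ_{j<k} J_kj(a_k, a_j) ),

with per-position fields h_k(a) and directed, strictly triangular couplings
J_kj(a, b) for j < k.  The parameterization has the same parameter count as
a pairwise Potts model but, unlike it, yields exact normalized sequence
probabilities: each conditional carries its own local partition function
z_k(prefix) over q terms.  Consequently the statistical energy E = −log P is
exact (it contains the log z_k terms, not just the raw parameters), ancestral
sampling gives i.i.d. sequences, and entropies and log-odds ratios are
directly computable.

The soft-max is over-parameterized (adding a constant to an h_k row, or to a
column J_kj(·, b), leaves every conditional unchanged).  No explicit gauge
is fixed; the L2 regularization selects one implicitly.  A numerical test
asserts this invariance of predictions; it means raw parameter values are
not comparable across implementations even when predictions agree.

## Site order

The factorization is valid for any column permutation, but the fitted model
depends on it.  Supported orders: *entropic* (default; columns sorted by
increasing empirical entropy s_i = −Σ_a f_i(a) log f_i(a), computed from
reweighted, pseudocount-free frequencies, ties broken by column index),
*direct* (native order), seeded *random*, and user-supplied permutations.
No search over orders is performed; the trainer's reported mean
log-likelihood allows comparing user-chosen orders.  All public inputs and
outputs (sequences, ΔE rows, contact indices) are in original alignment
coordinates; the permutation is internal to the model object.

## Training

Each position appears in exactly one conditional, so the weighted mean
log-likelihood decomposes into L independent soft-max regressions.  Per
site the objective (maximized) is

    (1/Meff) Σ_m w_m log P(a_k^m | prefix^m) − λ_h ‖h_k‖² − λ_J ‖J_k‖²,

with the exact gradient being the difference of empirical and model-averaged
moments minus 2λ·parameter.  Optimization is scipy's L-BFGS-B (the
low-storage BFGS method, unbounded) from a zero start, with gradient
∞-norm tolerance 1e−5 and at most 500 iterations per site; `ftol` is set
negligibly small so the gradient criterion governs.  The fits are
deterministic: refitting identical inputs is bit-identical.  The L per-site
problems are independent and could run concurrently; they are executed
sequentially, which trivially satisfies the equals-sequential contract.

Conventions that the literature leaves open, fixed here for
reproducibility:

- the likelihood is **mean**-normalized (1/Meff), so the regularization
  presets are comparable across family sizes;
- penalties are λ·Σ(param²) with **no 1/2 factor**;
- presets: `generative` λ_J = 1e−4, λ_h = 1e−6 (best statistics
  reproduction); `effects_contacts` λ_J = 1e−2, λ_h = 1e−4 (stronger
  shrinkage for mutational effects and contact maps).

The first position in the order is unconditioned; with λ_h = 0 its fields
are the closed form h(a) = log f(a) + const (frequencies floored at 1e−12,
the constant chosen to zero the mean), otherwise the same optimizer runs on
fields alone.

## Reweighting and empirical statistics

Sequence m gets weight w_m = 1 / #{m′ : identity(m, m′) ≥ θ}, θ = 0.8 by
default, identity being the fraction of equal codes over all L columns with
gap–gap agreements counting as matches (plain Hamming identity; the
convention is a config-level choice).  Meff = Σ w_m.  Reweighting can be
disabled (θ = None → unit weights), which is used when training on i.i.d.
synthetic samples where neighborhood weighting is a no-op in expectation but
O(M²L) to compute.

Frequencies mix with a uniform pseudocount α: f_i = (1−α)·(weighted
counts)/Meff + α/q (α/q² for pairs).  Training-side statistics and the
entropic ordering use α = 0 so that ordering reflects raw conservation; the
profile baseline defaults to α = 0.01 so its log-probabilities stay finite
on unseen residues.  Connected correlations follow the standard
subtractions; the three-point tensor is O(L³q³) and is therefore evaluated
on a seeded uniform subsample of (i<j<k, a, b, c) tuples (default 1e5; the
Pearson agreement is stable under this subsampling).

## Mutational effects, epistasis, contacts

ΔE(a_i→b) = E(mutant) − E(reference) with one background sequence (default:
the first MSA record).  The scan is computed incrementally — mutating model
position p leaves conditionals before p and every z_k with k ≤ p unchanged,
so only the chosen-state term at p and the (logit, z) pairs downstream of p
are recomputed — and is tested equal to the naive full-energy difference to
1e−10.  Epistasis ΔΔE = ΔE(double) − ΔE(i) − ΔE(j) uses batched exact
energies (three energy differences, no approximation).  Per-pair q×q ΔΔE
blocks act as effective couplings: each is shifted to the zero-sum gauge
(row means, column means, grand mean) over the retained states — the gap
state is excluded by default, the common DCA practice, and both the gap
convention and the minimum separation (default |i−j| ≥ 5, 2 in the
small fixtures) are exposed in the API.  Frobenius norms are corrected by
APC with means over off-diagonal entries.  A single reference background is
used rather than averaging over all M sequences; on the synthetic fixtures
the ranking is insensitive to the reference (Spearman > 0.99 between two
references).

## Entropy and sequence space

S = <E>_P is estimated from n i.i.d. samples (default 1e4) with standard
error s/√n; an enumeration oracle (−Σ P log P over all q^L sequences, cap
default 1e6 states, configurable) validates it on small models, and the
profile model's closed form Σ_i s_i validates the independent-site case.
Sequence-space bookkeeping is pure log10 arithmetic: log10 N = L·(S/L)/ln 10
against log10 q^L, so no overflow at any protein scale.

## Synthetic data

The fixtures module generates every study condition from seeded ground
truth:

- **random autoregressive models** — Gaussian fields and couplings at
  chosen scales and topology; coupling scale 0 gives an independent-site
  model;
- **exact Potts families** — a pairwise Potts distribution over all q^L
  states built by tensor broadcasting, sampled exactly by inverse-CDF (no
  MCMC).  Contact-recovery runs use L = 12, q = 4, M = 2·10⁴ with six
  coupled pairs of unit Gaussian blocks at separation ≥ 2, chosen as a
  site-disjoint random matching so that pair scores are not confounded by
  hub sites (APC deliberately suppresses shared-site signal);
- **two subfamilies** — a shared backbone model with field *and* coupling
  perturbations at a few divergent sites, so the subfamilies differ in
  covariation as real subfamilies do, plus disjoint-seed train/held-out
  splits;
- **two clusters** — a 50/50 mixture of sharp profiles for the PCA
  projection checks.

What the fixtures do not emulate: phylogenetic correlation between
sequences (samples are i.i.d.; reweighting is exercised only on
duplicates-style inputs), realistic gap patterns, and alignment errors.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under i.i.d. sampling, not performance on natural
alignments.

## Problem sizes and numerical choices

Self-check experiments use deliberately small instances so every claim has
an exact or statistical oracle: enumerable models (q^L ≤ 4096) for
normalization; an L=4, q=3, M=20 toy for finite-difference gradient checks
(step 1e−5) and λ=0 moment conditions; L=8, q=4 with 5·10⁴ samples for
conditional-distribution recovery (mean total-variation < 0.03 over 100
random prefixes, fitted with the truth's site order so conditionals are
directly comparable); 10 small random models for entropy agreement within
3 standard errors.  Log-sum-exp with max subtraction is used in every
partition function; probabilities and entropies are in nats throughout
(entropy densities of natural families are ~1.4 nats/site on this scale).
Model archives store little-endian float64 arrays plus JSON metadata in a
zip with fixed timestamps, so identical models serialize byte-identically.

## Known limitations

No deeper (multi-layer) conditionals; no optimization over the L! site
orders; no temperature or annealed sampling; no conditional in-filling of
partial sequences; multi-mutant scans beyond double mutants are not
provided.  Contact scores require the L·(L−1)/2 double-mutant scans, which
is exact but O(L²q²) energy evaluations; for long alignments this is the
dominant cost.
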