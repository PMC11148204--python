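# Methods

## Model and assumptions

A *functional module* is a set S of observable components that are
conditionally independent of all other observable components given a
single scalar interface variable y. The package tests modularizations —
families of modules that are flat (pairwise disjoint) or nested
(pairwise disjoint or contained) — under two assumptions: (i) only the
mean values of components and interfaces carry functional meaning, and
(ii) each interface is binary, or equivalently the mean of every
variable downstream of an interface is linear in the interface mean.
Probabilistic Boolean networks satisfy both by construction.

For zero-mean components the law of total expectation turns every mixed
moment E[s_k s_l s_ref] into a scalar product of two-dimensional vectors
indexed by the binary interface state. Inside a module all such vectors
are collinear, so the ratios

    B_kl = E[s_k s_l s_ref] / (E[s_k s_ref] E[s_l s_ref])

share one value across k ∈ S for each outside component l. A distinguished
*reference component* s_ref = s_d belongs to no module; it anchors the
denominators and makes flat and non-flat nested families distinguishable.
Each module contributes one equality constraint per outside component;
constraints from different modules that share a ratio index are merged
transitively (union–find), producing a partition {X_c} of the
d^(X₀) = (d−1)(d−2)/2 ratio indices. Unconstrained indices are kept as
singleton sets: they cancel exactly between the two sums of the statistic,
which makes the gamma shape ζ = ½(d^(X₀) − d^(X)) equal half the number of
independent equality constraints and gives T ≡ 0 for the vacuous test. A
*purely linear* module additionally equalizes all above-diagonal entries
of its own submatrix; the fully linear model ties every ratio index into
one set (ζ = ½(d^(X₀) − 1)).

## Estimation

With N samples (N even; an odd trailing sample is dropped with a
warning), the numerator of each ratio is the mean of odd-sample triple
products and the denominator the mean of products that pair the first
and second halves of the recording, so that a single product term
estimates the *product of two second moments*. Acquisition order is used
verbatim — no shuffling — so results are bit-reproducible from the input
file. The 2×2 per-term covariance blocks Σ′ between any two ratios are
plain sample covariances over the N/2 terms.

Ratios with weak denominators are unusable: the estimate b̂₁/b̂₂ has no
finite expectation when b̂₂ can approach zero. The signal-to-noise
statistic ϱ = b̂₂ / SE(b̂₂) gates each ratio; |ϱ| < θ (strict) sets the
ratio to 0 and its variance to +∞ (1/∞ := 0 wherever the inverse is
consumed). The default θ = 5 guarantees finite moments for approximately
normal estimates; the regulatory-network variant uses θ = 0.5, because
expression correlations are weak and the variant tolerates cutoffs by
treating them as inconclusive (p = 1). Surviving ratios get the
delta-method variance, optionally inflated by the finite-sample factor

    λ(ϱ) = ξ₀ (1 + Σ_{n=1..5} ξ_n (ϱ/6)^(−2n)),
    (ξ₀…ξ₅) = (1.367, 2.047, 4.735, −1.923, −1.231, 2.790),

which approaches ξ₀ = 1.367 for strong denominators. The asymptotic mode
(λ = 1) is exact in the large-N limit and is what the calibration tests
exercise.

## Decision rule

T is compared to the upper tail of Γ(ζ, 1) (evaluated via the
regularized incomplete gamma function, accurate far below 10⁻¹⁰). Two
further corrections keep the test conservative rather than exact:

- **λ^max** — constrained ratios estimated from shared components are
  positively correlated, which *deflates* T under the null but can
  inflate it under mild violations. Scaling Σ̂ by the largest eigenvalue
  of its correlation submatrix over the constrained, surviving ratios
  bounds the worst case. Cut-off ratios and singletons carry a zero
  scaler and drop out; with no constrained surviving ratio the factor is
  1 (the test is vacuous there anyway).
- **α^min** = 1 − erf((θ−1)/√2)^{d^(X₀)} · erf(6/√2)^{d^(X₀)} — the
  unavoidable error mass of the cutoff rule. The nominal level α* must
  exceed it; testing proceeds at α^Γ = (α* − α^min)/(1 − α^min), divided
  by the number d^H of candidates tested on the same samples. For θ ≤ 1
  the bound is vacuous and α^min = 0.

Because of these corrections the test is *valid but conservative*: on
the five-population benchmark the true nested modularization is rejected
in 0/500 replicates at an overall level of 0.01, and candidates whose
only violated equality is small relative to its standard error can
survive moderate recording lengths. Power against the fully linear model
rises from ≈0 at N = 500 to ≈1 at N = 4500.

## The five-population benchmark network

The synthetic-data generator reproduces the proof-of-principle circuit:
five observable binary variables x₁…x₅ (states {1,2}) and two latent
interfaces. x₄ is a fair coin; x₃ follows x₄ with fidelity 0.85;
y₁ = AND(x₃,x₄) gates the module {3,4}; x₂ follows y₁; y₂ (2 with
probability 0.85 when y₁ = x₂ = 2, certainly 2 when y₁ ≠ x₂, else 1)
gates {2,3,4}; x₁ follows y₂; x₅ = AND(x₁,y₂) is the reference. Each
population holds 10 neurons firing at 5 Hz (state 1) or 25 Hz (state 2)
in 200 ms bins, so population counts are Poisson with mean 10 or 50; a
15-minute recording gives N = 4500 bins. The point process behind the
counts is not dictated by the circuit definition; independent Poisson
neurons are assumed, and only the conditional count means enter the
method's assumptions. With seven binary variables the joint distribution
is enumerated exactly (128 configurations), yielding closed-form count
moments, the population B matrix, pairwise correlations (minimum
off-diagonal 0.401, e.g. corr(s₃,s₄) = 280/430 ≈ 0.651) and the optimal
linear predictor of x₅ from x₁…x₄ (R² = 0.787). These oracles back the
unbiasedness, consistency and equality-structure tests.

What the generator does *not* emulate: temporally correlated states
(bins are i.i.d.; real recordings need the autocovariance gate below),
non-Poisson count dispersion, unequal population sizes, and non-binary
interfaces. Passing tests on this benchmark therefore demonstrate the
statistical machinery, not robustness to those real-data features.

**Surrogates.** Linear surrogate data permute each component
independently across bins (destroying all cross-dependencies), scale to
unit variance, then mix with the Cholesky factor of the original sample
covariance. The surrogate matches the recorded correlation matrix but
satisfies every linear modularization; on surrogates the fully linear
candidate is retained at nominal rates. Whether to standardize before
recoloring is exposed as a flag (default on: recoloring non-whitened
data would give covariance L·D·Lᵀ instead of the intended Σ̂).

**Candidate enumeration.** All families of subsets of the non-reference
components with each subset of size ≥ 2, a proper subset of the
non-reference set, and pairwise disjoint-or-nested. Modules never
contain the reference and never equal the full non-reference set — such
"modules" impose zero testable constraints, and this convention is the
one that yields exactly 25 candidates for d = 5. The canonical order
(module count, then lexicographic) fixes the labels M1…M25; the
candidates consistent with the benchmark circuit are M8 = {{2,3,4}},
M10 = {{3,4}} and M25 = {{3,4},{2,3,4}}. Enumeration is capped at 24
components.

## Regulatory-network re-ranking

For a four-gene subnetwork (TFs s₁, s₂; TGs s₃, s₄ with s₄ as
reference) a single module containing both TFs forces the two ratios
b_k = E[s_k s₃]/E[s_k s₄] to coincide (one equality set, ζ = ½). The two
ratios are estimated on disjoint halves of the samples, which removes
their correlation *by construction* — the same device that makes the
disjoint-half statistic exactly Γ(½, 1)-calibrated, as the null
calibration test verifies (KS against uniform p-values, 2000 replicates
at N = 10⁴). The asymptotic variance (λ = 1) is used throughout this
variant.

Given a ranked interaction list with artificial p-values rank/N, a
subnetwork is *sufficiently connected* when at least three of its four
TF–TG edges are in the set of most likely interactions, including both
edges of the *putative interface TF* (the TF owning the single most
likely of the four edges; label order breaks ties). Each edge of the
other TF is then corrected by p ← max(p, c·p_test), combining multiple
subnetworks on one edge by the maximum. The scaling factor c is the
p-value at the *boundary* of the most-likely set (its largest member).
This is a deliberate design choice: c must be large enough for the
correction to act at all — with c equal to the smallest p in the set,
c·p_test can never exceed any p in the list and the correction would be
an exact no-op — while the boundary value caps the demotion so that an
edge with no evidence against its module lands at, never past, the set
whose members licensed the test. With the set equal to the whole list
the rule reduces to the plain conservative p ← max(p, p_test). The
roles of the two TGs follow label order; an option tests both
orientations and keeps the maximum p (off by default).

The most-likely-set size is the method's only free parameter; when a
gold standard is available it is chosen on a holdout of every 8th sample
by maximizing holdout-corrected AUPR (the holdout construction is given;
the AUPR criterion is this package's choice). Evaluation uses step-wise
precision–recall integration and ROC area (scikit-learn), appending
gold edges missing from the list in seeded random order; the challenge
summary scores are score_ROC = ½Σ(−log₁₀ p_ROC,i), likewise score_PR,
and their mean, with the null-distribution p-values supplied by the
user. Indirect TF–TG dependencies are labeled *nonremovable* when the
target's mediating gold regulators include two or more interdependent
TFs (a path between them or a shared upstream regulator) — a structural
operationalization kept in one function so it can be swapped.

## Numerical choices and degenerate inputs

- Variance estimates that come out (slightly) negative by cancellation
  are clipped to 0; T is clipped to 0 from below.
- Σ′₂₂ = 0 with b̂₂ ≠ 0 is treated as |ϱ| = ∞ (ratio kept, λ = ξ₀);
  with b̂₂ = 0 the cutoff branch applies.
- Equality-set weights that sum to zero (all members cut off) contribute
  0 to the between-set sum.
- p-values use `scipy.special.gammaincc` directly; no sampling.
- The enumeration DFS and the union–find merge are deterministic;
  permuting the module list cannot change the partition.
- All simulation entry points take a seed or `numpy.random.Generator`;
  identical seeds give bit-identical outputs.

## Problem sizes used in the shipped checks

Replication counts were chosen to keep the full suite fast while
leaving comfortable statistical margins: 500 replicates for the type-I
rate (0 rejections observed, binomial upper bound well below 0.01), 60
replicates per recording length for the power curves, 2000 replicates
at N = 10⁴ for null calibration, 3000 replicates for estimator
unbiasedness (|z| < 3), and 20 planted-network replicates at N = 800
for the re-ranking recovery property.

## Known limitations

- Correlated constrained ratios make the nested-path statistic
  stochastically smaller than Γ(ζ, 1) under the null; with the λ^max
  bound the test stays valid but loses power. Candidates violating only
  one small-magnitude equality may need recordings several times longer
  than 15 minutes to be rejected reliably.
- Interface variables with four or more states, and the sharper
  correlation correction that replaces the eigenvalue bound, are out of
  scope.
- The autocovariance check (`check_autocorrelation`) only *gates*
  non-i.i.d. data; no time-series correction is applied.
- The re-ranking pipeline tests subnetworks built from the most-likely
  set only; TF–TF interactions are excluded from correction.
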