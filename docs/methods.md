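# Methods

## Model

A hidden Markov model λ = (N, A, θ, π) over states {1..N} with a single
univariate Gaussian emission density per state, L_j(y) = N(y | μ_j, σ_j²).
Although a shared variance would suffice for the homoscedastic data the
method targets, the implementation carries a per-state variance
throughout (the block exponent and the M-step are defined per state, and
K-means initialization naturally produces per-state spreads).  All
probability computations are done in log space; sums of probabilities
use the log-sum-exp trick with the per-step maximum factored out, so no
scaling coefficients are needed and likelihoods of sequences with
hundreds of thousands of observations pose no underflow risk.

## Wavelet compression

The observation sequence is modeled as y = f + ε with f piecewise
constant and ε i.i.d. N(0, σ²).  The orthonormal Haar detail
coefficients of such a signal are N(0, σ²) away from jumps; zeroing
every coefficient with |d| ≤ λ_u = √(2 ln T)·σ (the universal threshold)
removes the noise, and the discontinuities of the reconstruction mark
candidate jumps.  σ is estimated as median(|finest details|)/0.6745 —
the MAD estimator, consistent for a Gaussian and robust to the few
jump-crossing coefficients — unless the caller supplies it (e.g. the
smallest emission standard deviation of a known model).

**Transform.**  The analysis is a lifting pass: levels are processed
finest to coarsest, each element carrying the *sum* of its original
span.  A pair with sums (S_a, S_b) over spans (n_a, n_b) produces the
unbalanced-Haar detail d = (S_a/n_a − S_b/n_b)·√(n_a n_b/(n_a+n_b)),
which reduces to (a−b)/√2 for equal spans, is exactly zero on constant
input for *any* spans, and has variance σ² under i.i.d. noise at every
level.  Odd-length levels carry their last element up unchanged.  This
handles arbitrary T in O(T) with no padding — padding would manufacture
phantom detail coefficients (hence spurious breakpoints) at the sequence
end, and so would a naive carry of orthonormally scaled values, which is
why the sum representation is used.  The inverse is exact to rounding;
round-trip identity is property-tested on lengths 1–257.

**Breakpoints.**  Every detail with |d| > λ_u contributes the position
where its wavelet changes sign (its support center).  Because a small
jump is often detected only by a coarse wavelet whose center may lie far
from the jump, each surviving coefficient is additionally *localized* by
descending the wavelet tree: at each finer level the child (left or
right support half) with the larger |detail| is followed down to the
finest level, and the centers visited are emitted as well.  This
descent is O(log T) per surviving coefficient, stays entirely within the
transform, and empirically reduces the worst-case evaluation error on
the benchmark grid by roughly a factor of two (boundary misplacement,
not missed jumps, dominates the error otherwise).  Breakpoints are
deduplicated and sorted; blocks are the runs between consecutive
breakpoints, each carrying (n_w, Σ₁,ʷ, Σ₂,ʷ) computed in one pass.

Compression is performed **once** per sequence, before any HMM
computation, and the blocks stay fixed across EM iterations.  This is
the homoscedastic setting; adapting the threshold to state-dependent
variances during training is deliberately out of scope.

## Compressed recursions

Within a block no state switch is allowed (the *weak path assumption*:
transitions inside low-variation stretches contribute negligibly to the
likelihood).  The forward variable α_w(i) refers to the end of block w:

    α_1(j) = π_j e^{E_1(j)},   α_w(j) = [Σ_i α_{w−1}(i) A_ij] e^{E_w(j)},

with E_w(j) as in the README.  Degenerate case: A_jj = 0 (a topology
that forbids self-loops) makes any block with n_w > 1 unreachable in
state j — the exponent is −∞ rather than an error, so decoding stays
well-defined; for n_w = 1 the (n_w−1)·ln A_jj term is exactly 0.

The backward recursion mirrors it (β_W ≡ 1); Viterbi replaces the sum
with a max (its block recursion is the natural max-analogue of the
forward one, validated against singleton-block identity and brute-force
enumeration over block-constant assignments).  Argmax ties break toward
the smallest state index so decoded paths are reproducible.

The E-step quantities are *exact* posteriors of the block-constrained
model: γ_w(i) = α_w(i)β_w(i)/p is the posterior of block w being in
state i, and the block-summed pair posterior ξ_w(i,j) adds
(n_w−1)·γ_w(i) expected within-block self-transitions to the
cross-boundary term α_w(i) A_ij e^{E_{w+1}(j)} β_{w+1}(j)/p (the last
block has no outgoing boundary, so its off-diagonal ξ is identically 0).
Mixed products are assembled in log space and exponentiated only after
subtracting log p.  The M-step is then

    π̄_i = γ_1(i),
    Ā_ij = Σ_w ξ_w(i,j) / (Σ_w n_w γ_w(i) − γ_W(i)),
    μ̄_j  = Σ_w γ_w(j) Σ₁,ʷ / Σ_w γ_w(j) n_w,
    σ̄²_j = Σ_w γ_w(j)[Σ₂,ʷ − 2μ̄_j Σ₁,ʷ + n_w μ̄_j²] / Σ_w γ_w(j) n_w.

Because E-step and M-step are exact for the block-constrained model,
compressed Baum-Welch is a true EM and its likelihood trace is monotone
— asserted over 100 seeded runs.  Two consequences worth noting:
π̄ = γ of the *first block*, which is an approximation of the classical
γ_1 whenever n_1 > 1; and the variance update uses the updated mean μ̄_j
(the classical M-step does the same here — the two routes must coincide
exactly on singleton blocks, which is the central correctness test at
1e-9).

Transitions that are exactly zero in the input model remain exactly
zero through reestimation (their ξ numerator vanishes), so topology
constraints survive training.  A variance floor of 1e-8 guards against
collapse on degenerate clusters, and a state with zero posterior mass
keeps its previous parameters with a warning instead of producing NaNs.

## Simulation harness

`build_model` constructs ground-truth models by topology
(fully-connected, left-to-right with an absorbing final state, circular)
with self-transition probability 1 − 10N/T — so a sequence of length T
contains on average 10N state switches regardless of T — the remaining
mass uniform over allowed successors, unit variances, and means spaced
by Δμ = 6η where η = |μ_a − μ_b|/(3(σ_a+σ_b)) is the state separation:
η = 1 is an easy, well-separated instance, η = 0.1 a hard one.
`sample_sequence` is fully deterministic given a seed; replicate r of a
benchmark uses seed + r so any replicate is re-runnable in isolation.
Training starts are produced by K-means on the raw observations
(centers sorted ascending → initial means; within-cluster variances,
floored → initial variances; topology-uniform transitions; uniform π).

What the generator emulates — and does not: sequences are genuinely
HMM-sampled (not noise added to a fixed staircase), so block structure,
switch counts and overlap between emission densities are all realistic
for the model class.  It does not emulate heteroscedastic noise,
heavy-tailed noise, trends, or missing data; passing benchmarks say
nothing about those regimes.

## Benchmark problem sizes and expectations

The evaluation-error benchmark uses the full grid N ∈ {2,3,5,10},
η ∈ {0.1,…,1.0} at T = 100000 with 3 sequences per cell.  The metric
|Δ log p|/|log p| scales like 10N/T — the expected switch count is fixed
at 10N while |log p| grows with T — so the sequence length is part of
the quantity's definition, not a free knob; at T = 100000 the measured
maximum is 4e-3–7e-3 depending on the seed (worst cells: N = 10 at
low η).  The
convergence-acceleration benchmark uses N = 10, η = 0.1, T = 20000,
5 seeds, tol = 1e-3, cap 100 iterations: the classical trainer
typically hits the cap while the compressed one stops after 15–40
steps.  Parameter-recovery and monotonicity checks run at T = 20000 and
T = 200 respectively.

## Known limitations

* The compressed likelihood is an approximation with no one-sided
  guarantee; only its magnitude on compressible data is controlled.
* Uncompressible input (low self-transition probability, or noise
  variance comparable to all mean gaps) degrades to W ≈ T, where the
  compressed path is strictly slower than the classical one.
* Single training sequence only; no mixture or multivariate emissions.
* The static universal threshold assumes homoscedastic noise; with
  state-dependent variances the smallest σ should be supplied, at the
  cost of under-compression in high-variance regions.
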