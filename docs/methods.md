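# Methods

## Model

Residue substitution in each alignment column is a continuous-time Markov
chain on n states with generator Q: non-negative off-diagonal rates, rows
summing to zero. We assume time reversibility — a distribution π with
π_i q_ij = π_j q_ji — and parametrize Q by the strictly-upper-triangular
entries of the symmetrized generator S plus the vector √π:

    Q = diag(√π)^{-1} S diag(√π),   π_i = (√π_i)² / Σ_k (√π_k)².

The diagonal of S is not free; it is set so that the rows of Q sum to
zero, which makes S (with that diagonal) exactly similar to Q. Detailed
balance is then automatic for any non-negative exchangeabilities. Neither
Q nor π depends on the scale of √π, so √π is left unconstrained positive
rather than normalized; the flat scale direction has zero gradient and is
harmless to the optimizer. Entries of √π below 1e-10 are clamped to 1e-10
on entry to keep the similarity transform well conditioned, and the
gradient of a clamped coordinate is defined as zero (the subgradient of
the clamp on its flat side). Parsing, construction and validation live in
`reversible_model`.

Because S is symmetric, `numpy.linalg.eigh` gives an orthogonal
B Λ Bᵀ = S, hence the real diagonalization Q = A Λ A^{-1} with
A = diag(√π)^{-1} B and A^{-1} = Bᵀ diag(√π) — no general-matrix
eigenproblem, no complex arithmetic, and the decomposition is reused for
every branch length that shares the generator.

## Derivatives of the matrix exponential

P(t) = A e^{Λt} A^{-1} costs two matrix multiplications once the
decomposition exists. The directional derivative of Q ↦ e^{Qt} along E is
A (A^{-1} E A ⊙ X(Λ,t)) A^{-1} where X is the divided-difference matrix
(diagonal t·e^{tλ_i}, off-diagonal divided differences of e^{t·}). The
reverse-mode adjoint — the transpose of that linear map under the trace
inner product — is A^{-T}(Aᵀ G A^{-T} ⊙ X(Λ,t)) Aᵀ. Both are implemented
in `matexp_grad`, with the adjoint's branch-local inner term exposed
separately so that a sum over branches sharing one model pays the outer
two multiplications once. The adjoint identity
⟨forward(M), N⟩ = ⟨M, adjoint(N)⟩ is enforced by test over random draws
at n ∈ {2, 4, 20} and t ∈ {0, 1e-6, 0.1, 1, 10}.

The naive quotient (e^{tλ_i} − e^{tλ_j})/(λ_i − λ_j) cancels
catastrophically for close eigenvalues — symmetric generators genuinely
produce near-degenerate spectra. We evaluate the mathematically identical
form

    X_ij = t · e^{t(λ_i+λ_j)/2} · sinch(t(λ_i−λ_j)/2),   sinch(z) = sinh(z)/z,

which is branch-free, continuous in the gap, and accurate from coincident
eigenvalues up through large gaps; tests pin it to a 50-digit
divided-difference oracle across gaps 1e-16…1e-1. One guard exists: for
|t·gap/2| > 350, where sinh alone would overflow before the product is
formed, the plain quotient (stable in that regime) is used instead.
Well-scaled generators never reach it. t = 0 needs no special case:
X(Λ,0) = 0 off the diagonal and P(0) = I fall out of the formulas.

Transition-matrix entries marginally outside [0, 1] from round-off
(within 1e-8) are clipped without renormalizing rows; anything worse
raises, since it indicates a broken decomposition rather than round-off.

## Pruning and the reverse pass

The forward pass (`felsenstein.pruning_forward`) is Felsenstein's
post-order recursion kept entirely in log space with logsumexp — no
per-node scaling factors. Leaf profiles are logs of non-negative vectors:
one-hot observed residues, indicator profiles for IUPAC nucleotide codes
and amino-acid B/Z, all-ones for gaps and X/N/?; a profile is an
indicator, not a renormalized distribution, matching standard pruning
practice. The root prior is the stationary π of the column's model — the
natural choice for a parametrization that exposes √π — and reversibility
makes the likelihood invariant to root placement (verified by a pulley
test), so unrooted/trifurcating inputs are handled by treating the
trifurcation as a multifurcating root. Multifurcations are supported
directly; zero-length branches use P(0) = I. Optional per-column integer
or real weights multiply each column's log likelihood and gradients,
supporting pattern compression.

The reverse pass walks the tree once in pre-order. Differentiating the
logsumexp recursion gives, for the edge above node u with parent v,
∂L/∂P(t_u)[a,b] = g_v[a] · exp(ℓ_u[b] − m_u[a]), where ℓ_u is u's log
partial vector, m_u the log message to v, and g_v the accumulated adjoint
of v's partials; the adjoint passed down is the product with P summed
over parent states. −∞ log-partials (impossible states under one-hot
leaves) are handled by masking 0 · e^{−∞−(−∞)} products to zero. Per-edge
∂L/∂P is reduced per model and pulled to ∂L/∂Q via the summed-inner-term
adjoint; branch-length gradients are ∂L/∂t = ⟨∂L/∂P, Q P(t)⟩. The root
term contributes ∂L/∂π, which is folded into the √π gradient along with
the chain rule through the build (and, when rate normalization is on,
through the mean-rate divisor μ = −Σ_i π_i q_ii). One subtlety: for a
column with no information (all-ones profiles) the free-parameter and
branch gradients vanish exactly, but the unconstrained matrix ∂L/∂Q
vanishes only modulo the row-sum gauge — its rows are constant, so every
admissible generator direction has zero directional derivative.

Everything is vectorized over columns; with a single global model the
per-edge transition matrices are computed once (the global fast path),
and a test pins this path to the general per-column machinery at 1e-12.

## Fitting

`fitting.fit` maximizes the log likelihood with SciPy's L-BFGS-B (no
bounds, memory 10, Wolfe line search), all positive parameters in log
space so the problem is unconstrained and positivity is structural.
Stopping uses the relative-improvement rule: an iteration that improves
the objective by less than `rel_improve_tol` (default 1e-6, i.e. 0.0001%)
terminates the fit; this is exactly L-BFGS-B's `ftol` semantics for
|L| ≥ 1. An optional L2 penalty on the log-parameters regularizes
column-specific fits; a penalty of zero takes a code path bitwise
identical to the unpenalized one.

Rate normalization (scale Q so −Σ π_i q_ii = 1) is applied per model,
default on for fitting and off for raw gradient evaluation. It removes
the scale of the exchangeabilities from the likelihood for every model
kind, which is what `count_free_parameters` counts: a global amino-acid
GTR has 190 − 1 + 19 = 208 identifiable parameters. We chose mean-rate
normalization over fixing one exchangeability to 1; the two conventions
give identical likelihood surfaces up to reparametrization, and
normalization keeps the parameter treatment symmetric. The optimizer
works in the redundant parametrization — the removed scale is a flat
direction with zero gradient, not an eliminated coordinate — so the
reported count is the identifiable dimension, not the vector length.
Initialization defaults to equal exchangeabilities and uniform π
(optionally jittered under the seed); optimization itself is
deterministic.

For a shared-S model with per-column π, note that per-model normalization
also equalizes the average substitution rate across columns, and that a
single column carries little information about its own π: unregularized
per-column estimates scatter widely around the truth even when all
columns share one generating model (their cross-column mean still
recovers it). The L2 penalty is the intended remedy; tests assert the
average-recovery and shrinkage behavior rather than tight per-column
agreement.

## Simulator

`simulate` generates test data natively. Topologies come from sequential
random coalescence (uniformly chosen lineage pairs merge until one root
remains) — the simplest exchangeable distribution; the engine is
topology-agnostic, so nothing downstream depends on this choice. Branch
lengths are i.i.d. exponential; the default mean of 0.1
substitutions/site puts pairwise divergences in the range typical of
curated protein alignments. Columns evolve by drawing the root from π and
each child from the parent's row of P(t_edge). Correctness is anchored by
distributional oracles: leaf-frequency stationarity, two-leaf joint
frequencies against π_a P(t1+t2)_ab, and monotone divergence in the
branch-length mean. The bundled 20-state model is a fixed seeded random
parameter set — synthetic, shaped like an empirical amino-acid matrix but
not estimated from data.

What the simulator does not emulate: indels (gaps appear only via
ambiguity handling, not an indel process), rate variation across sites
beyond explicit column-specific models, non-stationary or non-reversible
processes, and alignment error. Passing recovery tests therefore shows
the estimator is correct under the model, not that the model captures
real alignments.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to exercise every code path
while keeping the suite quick: gradient checks on 4–16 taxa at n ∈
{4, 20}, enumeration cross-checks on ≤ 6 leaves (the brute-force oracle
is exponential), and parameter-recovery fits at 64 taxa × 2000 columns ×
10 replicates, where the fitted exchangeabilities correlate with the
generating ones at r > 0.99. Central finite differences use step 1e-6;
agreement is asserted at 1e-6 relative with an absolute floor for
components near zero, where the difference quotient itself is round-off
limited. Ties and degenerate inputs — repeated eigenvalues, zero branch
lengths, zero exchangeabilities (absorbing chains), all-unknown columns,
clamped √π — are all exercised explicitly.

## Limitations

Non-reversible generators are out of scope (the adjoint formula itself
only needs diagonalizability, but the parametrization, root prior and
pulley invariance all lean on reversibility). No tree search, no
branch-length optimization loop (gradients are provided; an optimizer
over them is only exercised in tests), no rate-category mixtures beyond
what explicit column-specific models express, and no GPU path. The
IQ-TREE/RAxML convention Q = R diag(π) is not a first-class
parametrization; convert via s_ij = r_ij √(π_i π_j) (equivalently
R = diag(√π)^{-1} S diag(√π)^{-1}).
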