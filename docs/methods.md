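# Methods

## Model

Let `G ∈ {1..C}` be the true class (cause of death) and `A` a classifier's
predicted class. The estimand is `p`, the population distribution of `G` in
the target domain, observed only through (i) predicted-class counts
`v` on `N` unlabeled records and (ii) a C×C table `T` of (true, predicted)
counts on a small labeled set. The single transportability assumption is
that the conditional error rates `m_ij = P(A = j | G = i)` — the confusion
matrix `M` — are common to both sets; the class margins need not be (the
labeled set is typically hospital-based and unrepresentative, which is why
only the conditionals of `T` are modeled, never its margins).

Likelihood and priors:

```
v | M, p ~ Multinomial(N, M'p)
T_i* | M ~ Multinomial(n_i, M_i*),        i = 1..C
M_i*     ~ Dirichlet(γ_i (e_i + ε 1))
p        ~ Dirichlet(δ 1)
γ_i      ~ Gamma(α, β)
```

The row prior has two roles. First, its posterior mean under the labeled
data alone is, as `ε → 0`, the shrinkage estimator
`(1 − λ_i) T_i*/n_i + λ_i e_i` with `λ_i = γ_i / (n_i + γ_i)` — identity
(no correction) when a class has no labeled data, the raw error rates when
it has many. Second, because `γ_i` carries its own prior, the degree of
shrinkage is learned per row. Two limit results anchor the implementation
and are enforced by tests: with diagonal `T` the marginal posterior of `p`
tends (as `ε → 0`) to `Dirichlet(v + δ1)`, so calibration leaves an
apparently error-free classifier's estimate untouched; and in the joint
ensemble model, a labeled-set-perfect classifier makes the posterior
collapse onto that classifier's naive estimate regardless of the others.

## Samplers

All samplers share a data-augmentation core: latent counts `b_ij` split
each predicted-class total `v_j` across true classes
(`b_j ~ Multinomial(v_j, (m_ij p_i)_i / Σ_i m_ij p_i)`), which restores
Dirichlet conjugacy for both `M` rows (`Dirichlet(b_i* + T_i* + γ_i ε 1 +
γ_i e_i)`) and `p` (`Dirichlet(rowsums(B) + δ)`). The scales `γ_i` have a
nonstandard full conditional (a ratio of Gamma functions times the prior
and the row likelihood) and are updated by random-walk Metropolis on
`log γ_i` with the Jacobian term; the proposal scale (default 0.5) is
adapted during burn-in toward ~35% acceptance and frozen afterwards. Sweep
order is fixed: `B`, `M`, `p`, `γ`.

Ensemble variants: the *joint* model treats each record's K predictions as
one draw from the sparse distribution over observed combinations
(`w_j = Σ_i p_i Π_k m^(k)_{i j_k}` under conditional independence given
`G`), allocating each combination's count across true classes per sweep;
storage and cost scale with the number of *observed* combinations, never
`C^K`. The *independent* model (default — faster, and in practice equally
good at favoring the more accurate classifier) runs the single-classifier
augmentation per channel and pools the latent true-class totals in the `p`
update. With K = 1 it executes the identical code path as the
single-classifier sampler, so equality there is structural, not
approximate.

Covariate variant: `p` is replaced by pattern-specific
`p_hi = softmax(x_h'β)_i` with `β_C = 0` (reference class = last in the
label space, configurable) and `β_i ~ N(m_0i, W_0i)` (defaults `0`, `25 I`
— weakly informative on the log-odds scale). After the same latent-count
augmentation, each `β_i` is conditionally Gaussian given one Polya-Gamma
variable per (pattern, class): `ω_hi ~ PG(n_h, x_h'β_i − c_hi)` with
`c_hi = logsumexp_{k≠i}(x_h'β_k)`, precision `X'Ω_iX + W_0i⁻¹` and linear
term `X'(κ_i + Ω_i c_i) + W_0i⁻¹ m_0i`, `κ_hi = Σ_j b_hij − n_h/2`. (The
`+Ω_i c_i` sign follows from expanding `κψ − ωψ²/2` at `ψ = x'β − c`; the
conjugate update matches the standard Polya-Gamma multinomial-logit
sampler, and an intercept-only fit is verified against the marginal model.)
Population-level CSMFs are recovered per draw as
`p_i = Σ_h (n_h/N) p_hi`; patterns with zero unlabeled records get weight
zero. Covariate-dependent confusion matrices are out of scope (an interface
hook exists in the design type, nothing more).

Polya-Gamma variates are drawn in-package (`vacalib/_polya_gamma.py`) from
the exact infinite sum-of-Gammas representation truncated at 200 terms with
the discarded tail replaced by its expectation; truncation error is below
~0.1% of the mean, ample for latent-variable augmentation, and the
implementation is validated against the closed-form PG moments.

## Defaults and numerical choices

| parameter | default | why |
|---|---|---|
| ε | 1e-3 | small enough that the Dirichlet-limit results hold to well within Monte-Carlo error; large enough that rows with zero off-diagonal counts still get proper Dirichlet updates |
| δ | 1 | uniform prior on the simplex; `δ = 0` allowed as an improper theorem-limit mode (warned; concentrations floored at 1e-12 if a class's latent total hits zero) |
| α, β | 1, 1 | prior mean 1 for each `γ_i`: shrinkage weight `λ_i ≈ 1/(n_i+1)`, i.e. essentially data-driven |
| chains / iterations | 3 × 5000, 50% burn-in | split-R̂ and ESS are reported, convergence advisory not enforced |
| initialization | `p = v/N` (floored at `1/(10C)`, renormalized), `M` = shrinkage estimate at `γ = 1`, `γ = 1` | |
| quantiles | type-7 (linear interpolation) | the common default |

Confusion-matrix draws are clipped at 1e-300 before logs so the `γ`
Metropolis target stays finite when a Dirichlet draw underflows. Label
matching is case-sensitive; classes absent from all inputs are retained in
the state. One master seed drives everything; per-chain seeds are spawned
deterministically from it.

Known limitation: like all data-augmentation samplers, mixing can be slow
along weakly identified directions — e.g. when a confusion row sends half
of one cause to another, the split of their combined mass is informed only
by the labeled set, and at large `N` the `p` update is nearly degenerate
given `B`. The worked example in the README shows exactly this (low ESS for
the Other/Sepsis pair); the remedy is longer chains, monitored through the
reported R̂/ESS.

## Synthetic-data generator

The generator reproduces the statistical structure of a confusion-channel
simulation design: CSMF pairs `(p_L, p_U)` are independent `Dirichlet(1)`
draws rejection-sampled into disparity bins by their CSMF accuracy
(low ≤ 0.4 < medium ≤ 0.6 < high; boundary values to the lower bin), and
records are generated either prediction-first (draw `A` from `q = M'p`,
then the truth from the Bayes-rule probabilities `α_ij ∝ m_ij p_i`) for a
single channel, or truth-first with conditionally independent channels for
K > 1 — the two orders define the same joint law, and a chi-square test in
the suite confirms their empirical equivalence. Built-in channels: `M1`
(identity), `M2` (two large systematic biases: 65% Diarrhea→Pneumonia, 50%
Sepsis→Other), `M3` (`0.6 I + 0.1 11'`: 10% on every off-diagonal).

What the generator deliberately does not emulate: symptom-level data
(~250 questionnaire items), real CCVA software, covariate-dependent error
rates, or within-channel heterogeneity. Passing tests therefore demonstrate
correct inference *under the channel model* — i.e., when the
transportability assumption holds exactly — not robustness to its
violation in real verbal-autopsy data.

`run_study` executes the scenario × channel × labeled-size grid. Each cell
pairs the cell's channel with a fixed companion channel (M3, or M2 when the
cell is itself M3) so ensemble estimators always combine classifiers of
different quality — the channel-world analogue of running two real
algorithms on the same records. The default harness uses 20 replicates per
cell and `N = 5000` (a deliberately desk-scale version of the design, which
used 100 replicates); sampler settings for study runs default to a single
chain of 1000 sweeps, which suffices because only the posterior mean is
scored.

## Oracles behind the tests

Three independent routes check the samplers: (1) the analytic
Dirichlet-limit results above, at `ε = 1e-6`, within 3 Monte-Carlo standard
errors (ESS-based); (2) for a C = 2 instance with tiny counts, exact grid
integration of the unnormalized posterior — the `γ_i` are first
marginalized into each row's effective prior by 1-D quadrature on a log
grid, leaving a 3-D midpoint integral over `(p_1, m_11, m_22)`; the
transfer table is chosen with all entries ≥ 1 so the `ε`-Dirichlet boundary
singularities are cancelled by the likelihood and the quadrature converges
(the test instance agrees with a 400k-sweep run to 4 decimal places);
(3) parameter recovery and direction checks on generator output, where the
truth is known by construction.
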