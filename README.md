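# vacalib

Bayesian transfer-learning calibration of population-level class
probabilities — built for estimating **cause-specific mortality fractions
(CSMF)** from computer-coded verbal autopsy (CCVA) predictions, and usable
for any label-shift problem with the same shape: a pre-trained classifier
scored on a large unlabeled target sample, plus a small labeled validation
set from the same target population.

## The problem and the model

A CCVA classifier trained elsewhere assigns a cause of death `A` to each of
`N` unlabeled deaths in a new population. The naive CSMF estimate is the
vector of predicted-class fractions `q̂ = v / N`. Unless the classifier is
error-free in the new population, `q̂` is biased for the true CSMF `p`:
marginally `q = M'p`, where `M` is the row-stochastic **confusion matrix**
`m_ij = P(A = j | G = i)` assumed transportable from a small labeled set of
`n` deaths with known causes (counts `T`, `t_ij` = true `i` predicted `j`).

The hierarchical model is

```
v | M, p  ~  Multinomial(N, M'p)
T_i*      ~  Multinomial(n_i, M_i*)
M_i*      ~  Dirichlet(γ_i (e_i + ε 1))     (shrinkage prior toward identity)
p         ~  Dirichlet(δ 1),   γ_i ~ Gamma(α, β)
```

The Dirichlet prior on each confusion row shrinks it toward the identity row
with data-adaptive weight `λ_i = γ_i / (n_i + γ_i)`: with no labeled data
the posterior mean of `p` collapses onto the familiar uncalibrated `v/N`
(exactly, in the `ε → 0` limit, for diagonal `T`), and with plentiful
labeled data it trusts the empirical error rates `t_ij / n_i`. Inference is
a data-augmented Gibbs sampler (latent counts allocating each `v_j` across
true causes), with random-walk Metropolis on `log γ_i`.

Three extensions share the same machinery:

* **Ensembles** (`K` classifiers, conditionally independent given the true
  cause): a *joint* model over sparse prediction combinations and a lighter
  *independent* model over the `K` marginal channels (the default).
* **Covariates**: `p` becomes a multinomial-logistic function of covariates,
  sampled conjugately via Polya-Gamma augmentation; population CSMFs are the
  covariate-weighted average of pattern-specific CSMFs.
* **Individual predictions**: per posterior draw,
  `P(G = i | A = j) ∝ m_ij p_i` turns population calibration into calibrated
  individual class probabilities.

Accuracy is scored by **CSMF accuracy**,
`CSMFA(p̂, p) = 1 − ‖p̂ − p‖₁ / (2(1 − min p))` (1 = perfect, 0 = worst
possible).

## Worked example

Simulate a hard setting — a biased classifier (65% of Diarrhea/Dysentery
deaths predicted as Pneumonia, 50% of Sepsis deaths predicted as Other) on a
population whose CSMF differs sharply from the labeled set's — then
calibrate:

```sh
vacalib simulate --scenario low --n-unlabeled 5000 --n-labeled 400 \
    --confusion M2 --seed 7 --outdir sim
vacalib calibrate --unlabeled sim/unlabeled.csv --labeled sim/labeled.csv \
    --chains 3 --iters 10000 --burnin 5000 --seed 1 --outdir fit
# posterior mean p: 0.0240 0.3668 0.0365 0.5727
```

`fit/summary.csv` (classes in sorted order: Diarrhea/Dysentery, Other,
Pneumonia, Sepsis):

```
parameter    mean      sd    q2.5     q50   q97.5    rhat       ess
p[0]       0.0240  0.0048  0.0160  0.0235  0.0348  1.0045  798.4517
p[1]       0.3668  0.0895  0.1832  0.3761  0.5265  1.1851   13.0208
p[2]       0.0365  0.0051  0.0257  0.0368  0.0458  1.0037  844.6042
p[3]       0.5727  0.0895  0.4130  0.5635  0.7564  1.1852   13.0252
```

The generating truth was `p_U = (0.0282, 0.3626, 0.0352, 0.5740)`. The
uncalibrated estimate `v/N = (0.051, 0.009, 0.301, 0.639)` scores
CSMFA 0.70; the calibrated posterior mean scores **CSMFA 0.99**, correctly
undoing both systematic biases. The wide, anticorrelated intervals for
Other/Sepsis (and their lower effective sample size) honestly reflect that
their split is identified only through the 400 labeled deaths.

The same inputs drive `vacalib ensemble` (columns `predicted_<name>`, one
per classifier), `vacalib covariate` (`--covariate region:categorical`),
and `vacalib metrics "0.5,0.5" "0.25,0.75"` → `0.666667`. Everything is
also available as a library (`vacalib.gibbs_single`, `vacalib.run_study`,
...); see `docs/methods.md` for the model details.

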