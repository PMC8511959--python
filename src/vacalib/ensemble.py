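"""Ensemble calibration combining K classifiers' predictions.

Two variants share the prior structure of the single-classifier model, with
one confusion matrix ``M^(k)`` (and shrinkage scales ``gamma^(k)``) per
classifier, all tied to the common CSMF ``p``:

* **joint** — models the full joint distribution of the K predictions per
  record under conditional independence given the true class, so a record
  predicted as the combination ``j = (j_1, ..., j_K)`` has probability
  ``w_j = sum_i p_i prod_k m^(k)_{i j_k}``.  Observed combinations are stored
  sparsely; memory never scales as C^K.
* **independent** — the computationally lighter default: models only the K
  marginal prediction distributions ``q^(k) = M^(k)' p``, pooling the latent
  true-class allocations across classifiers in the update of ``p``.

With K = 1 the independent model *is* the single-classifier model: both call
the same channel-sampler core, so chains agree bit-for-bit under a shared
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model_core import (
    Hyperparams,
    LabelSpace,
    PosteriorDraws,
    PredictionCounts,
    SamplerControl,
    SamplerError,
    TransferCounts,
    ValidationError,
    _LOG_FLOOR,
    _dirichlet_p_alpha,
    _init_p,
    _shrink_rows,
    check_confusion,
    check_csmf,
    log_gamma_conditional,
    run_channel_sampler,
)

__all__ = [
    "CombinationCounts",
    "tabulate_combinations",
    "gibbs_joint",
    "gibbs_independent",
    "ensemble_individual_posterior",
]


@dataclass(frozen=True)
class CombinationCounts:
    """Sparse counts of observed K-way prediction combinations.

    ``counts`` maps a tuple of K class indices to the number of unlabeled
    records with exactly that combination of predictions.  Only observed
    combinations are stored.
    """

    counts: Mapping[tuple[int, ...], int]
    K: int
    space: LabelSpace

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        for combo, y in self.counts.items():
            if len(combo) != self.K or y < 1:
                raise ValidationError(f"bad combination entry {combo}: {y}")

    @property
    def N(self) -> int:
        return int(sum(self.counts.values()))

    def marginal(self, k: int) -> PredictionCounts:
        """Marginal prediction counts ``v^(k)`` of classifier k."""
        v = np.zeros(self.space.C, dtype=np.int64)
        for combo, y in self.counts.items():
            v[combo[k]] += y
        return PredictionCounts(v=v, space=self.space)


def tabulate_combinations(
    preds: Sequence[Sequence[str]] | np.ndarray, space: LabelSpace
) -> CombinationCounts:
    """Tabulate the N×K matrix of predicted labels into sparse combination counts."""
    preds = np.asarray(preds, dtype=object)
    if preds.ndim != 2 or preds.shape[0] == 0:
        raise ValidationError("predictions must be a nonempty N×K matrix")
    N, K = preds.shape
    codes = np.column_stack([space.codes(preds[:, k]) for k in range(K)])
    counts: dict[tuple[int, ...], int] = {}
    for row in map(tuple, codes):
        counts[row] = counts.get(row, 0) + 1
    return CombinationCounts(counts=counts, K=K, space=space)


def _validate_ensemble_inputs(Ts: Sequence[TransferCounts], space: LabelSpace):
    for t in Ts:
        if t.space.classes != space.classes:
            raise ValidationError("all inputs must share one label space")
    if len({tuple(t.n_i) for t in Ts}) > 1:
        raise ValidationError(
            "transfer matrices must come from the same labeled records"
        )


def _run_joint_chain(seed_seq, combos, ys, T, hyper, control):
    """One chain of the joint-ensemble sampler.

    ``combos`` is (n_combos, K) column indices, ``ys`` the matching counts.
    Latent true-class counts are drawn per observed combination; confusion
    and CSMF updates mirror the single-classifier conjugate steps.
    """
    import math

    rng = np.random.default_rng(seed_seq)
    K, C = T.shape[0], T.shape[1]
    eps, delta = hyper.epsilon, hyper.delta
    n_combos = combos.shape[0]

    # marginal counts drive the initialization, as in the single model
    v = np.zeros((K, C))
    for k in range(K):
        np.add.at(v[k], combos[:, k], ys)
    p = _init_p(v)
    gamma = np.ones((K, C))
    M = np.clip(
        np.stack([_shrink_rows(T[k], gamma[k]) for k in range(K)]), _LOG_FLOOR, None
    )
    step = np.full((K, C), control.mh_step)

    n_kept = control.n_kept
    keep_p = np.empty((n_kept, C))
    keep_M = np.empty((n_kept, K, C, C))
    keep_g = np.empty((n_kept, K, C))
    acc = np.zeros((K, C))
    adapt_acc = np.zeros((K, C))
    adapt_window = 50
    n_acc_iters = 0
    kept = 0

    for it in range(control.n_iter):
        # per-combination latent allocation; conserve sum_i b_{j,i} = y_j
        # weights: (n_combos, C) with w_{j,i} = p_i prod_k m^(k)_{i, j_k}
        W = np.tile(p, (n_combos, 1))
        for k in range(K):
            W *= M[k][:, combos[:, k]].T
        s = W.sum(axis=1)
        if not (s > 0).all():
            bad = int(np.flatnonzero(s <= 0)[0])
            raise SamplerError(
                f"all-zero weights for observed combination {tuple(combos[bad])} "
                f"at iteration {it}"
            )
        B_combo = np.empty((n_combos, C))
        for c_idx in range(n_combos):
            B_combo[c_idx] = rng.multinomial(ys[c_idx], W[c_idx] / s[c_idx])

        # channel-wise confusion updates
        for k in range(K):
            counts_k = np.zeros((C, C))
            np.add.at(counts_k.T, combos[:, k], B_combo)
            for i in range(C):
                a = counts_k[i] + T[k, i] + gamma[k, i] * eps
                a[i] += gamma[k, i]
                M[k, i] = np.clip(rng.dirichlet(a), _LOG_FLOOR, None)

        p = rng.dirichlet(_dirichlet_p_alpha(B_combo.sum(axis=0), delta))
        p = np.clip(p, _LOG_FLOOR, None)

        for k in range(K):
            for i in range(C):
                cur = gamma[k, i]
                l_cur = log_gamma_conditional(cur, M[k, i], i, hyper)
                prop = math.exp(math.log(cur) + step[k, i] * rng.standard_normal())
                l_prop = log_gamma_conditional(prop, M[k, i], i, hyper)
                log_ratio = l_prop - l_cur + math.log(prop) - math.log(cur)
                if math.log(rng.uniform()) < log_ratio:
                    gamma[k, i] = prop
                    adapt_acc[k, i] += 1
                    if it >= control.n_burnin:
                        acc[k, i] += 1

        if control.adapt and it < control.n_burnin and (it + 1) % adapt_window == 0:
            rate = adapt_acc / adapt_window
            step *= np.exp((rate - 0.35) / math.sqrt((it + 1) / adapt_window))
            adapt_acc[:] = 0
        if it >= control.n_burnin:
            n_acc_iters += 1
            if (it - control.n_burnin) % control.thin == 0:
                keep_p[kept] = p
                keep_M[kept] = M
                keep_g[kept] = gamma
                kept += 1

    return keep_p[:kept], keep_M[:kept], keep_g[:kept], acc / max(n_acc_iters, 1)


def gibbs_joint(
    y: CombinationCounts,
    Ts: Sequence[TransferCounts],
    hyper: Hyperparams | None = None,
    control: SamplerControl | None = None,
) -> PosteriorDraws:
    """Fit the joint ensemble model over sparse prediction-combination counts."""
    hyper = hyper or Hyperparams()
    control = control or SamplerControl()
    if y.K < 2:
        raise ValidationError(
            "joint ensemble requires K >= 2 classifiers; use gibbs_single for K = 1"
        )
    if len(Ts) != y.K:
        raise ValidationError("need one transfer matrix per classifier")
    _validate_ensemble_inputs(Ts, y.space)

    combos = np.array(sorted(y.counts.keys()), dtype=np.intp)
    ys = np.array([y.counts[tuple(c)] for c in combos], dtype=np.int64)
    T = np.stack([t.T for t in Ts])

    seeds = np.random.SeedSequence(control.seed).spawn(control.n_chains)
    chains = [_run_joint_chain(s, combos, ys, T, hyper, control) for s in seeds]
    return PosteriorDraws(
        p=np.stack([c[0] for c in chains]),
        M=np.stack([c[1] for c in chains]),
        gamma=np.stack([c[2] for c in chains]),
        accept=np.stack([c[3] for c in chains]),
        space=y.space,
        hyper=hyper,
        control=control,
    )


def gibbs_independent(
    vs: Sequence[PredictionCounts],
    Ts: Sequence[TransferCounts],
    hyper: Hyperparams | None = None,
    control: SamplerControl | None = None,
) -> PosteriorDraws:
    """Fit the independent ensemble model (K marginal prediction channels).

    Each classifier contributes its own latent allocation and confusion
    update exactly as in the single-classifier sampler; the CSMF update pools
    latent true-class totals across classifiers.  For K = 1 this reduces
    exactly (bit-for-bit under a shared seed) to ``gibbs_single``.
    """
    if len(vs) != len(Ts):
        raise ValidationError("need one transfer matrix per classifier")
    return run_channel_sampler(vs, Ts, hyper, control)


def ensemble_individual_posterior(
    Ms: Sequence[np.ndarray], p: np.ndarray, combo: Sequence[int]
) -> np.ndarray:
    """Posterior class probabilities given one record's K predicted classes.

    Under conditional independence, ``P(G = i | a = j) ∝ p_i prod_k
    m^(k)_{i j_k}``.
    """
    p = check_csmf(p)
    if len(Ms) != len(combo):
        raise ValidationError("need one confusion matrix per predicted class")
    w = p.copy()
    for M, j in zip(Ms, combo):
        w = w * check_confusion(M)[:, j]
    s = w.sum()
    if s <= 0:
        raise ValidationError(
            f"prediction combination {tuple(combo)} has zero probability "
            "under the model"
        )
    return w / s
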