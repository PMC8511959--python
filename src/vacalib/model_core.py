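"""Core data structures and the single-classifier calibration sampler.

The estimand is the population-level class-probability vector ``p`` (in the
verbal-autopsy setting, the cause-specific mortality fractions, CSMF) of a
*target* population for which we have

* abundant unlabeled records scored by a pre-trained classifier — summarised
  by the predicted-class count vector ``v`` (``N = sum(v)`` records), and
* a very small labeled set of (true class ``G``, predicted class ``A``)
  pairs — summarised by the C×C transfer-count matrix ``T``.

The model links the two through a row-stochastic confusion matrix
``M`` with entries ``m_ij = P(A = j | G = i)`` assumed transportable between
the labeled and unlabeled sets, so the classifier's marginal prediction
distribution is ``q = M' p``.  A hierarchical prior shrinks each row of ``M``
toward the corresponding identity row with a data-adaptive weight
``lambda_i = gamma_i / (n_i + gamma_i)``, so that with little or no labeled
data the calibrated estimate collapses onto the uncalibrated plug-in
``v / N``, and with plentiful labeled data it trusts the empirical error
rates ``t_ij / n_i``.

Inference is by a data-augmented Gibbs sampler: latent counts ``b_ij``
allocate each predicted-class total ``v_j`` to true classes, restoring
Dirichlet-multinomial conjugacy for ``M`` and ``p``; the shrinkage scales
``gamma_i`` are updated by random-walk Metropolis on the log scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ValidationError",
    "SamplerError",
    "LabelSpace",
    "PredictionCounts",
    "TransferCounts",
    "Hyperparams",
    "SamplerControl",
    "PosteriorDraws",
    "check_confusion",
    "check_csmf",
    "tabulate_predictions",
    "tabulate_transfer",
    "mom_confusion",
    "shrink_confusion",
    "compose_q",
    "log_gamma_conditional",
    "gibbs_single",
    "individual_posterior",
]

_SIMPLEX_TOL = 1e-10
_LOG_FLOOR = 1e-300  # keeps log-densities finite after Dirichlet underflow


class ValidationError(ValueError):
    """Invalid user input (labels, shapes, configuration)."""


class SamplerError(RuntimeError):
    """Numerical failure inside an MCMC run."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelSpace:
    """Ordered set of the C class names shared by truth and predictions."""

    classes: tuple[str, ...]

    def __init__(self, classes: Sequence[str]):
        classes = tuple(str(c) for c in classes)
        if len(classes) < 2:
            raise ValidationError("label space needs at least 2 classes")
        if len(set(classes)) != len(classes):
            raise ValidationError(f"duplicate class names in {classes}")
        object.__setattr__(self, "classes", classes)

    @property
    def C(self) -> int:
        return len(self.classes)

    def index(self, label: str) -> int:
        try:
            return self.classes.index(str(label))
        except ValueError:
            raise ValidationError(
                f"label {label!r} not in label space {self.classes}"
            ) from None

    def codes(self, labels: Sequence[str]) -> np.ndarray:
        """Map a sequence of labels to integer codes, rejecting unknowns."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        out = np.empty(len(labels), dtype=np.intp)
        for r, lab in enumerate(labels):
            try:
                out[r] = lookup[str(lab)]
            except KeyError:
                raise ValidationError(
                    f"label {lab!r} (row {r}) not in label space {self.classes}"
                ) from None
        return out


@dataclass(frozen=True)
class PredictionCounts:
    """Predicted-class counts ``v`` on the unlabeled set; ``N = sum(v)``."""

    v: np.ndarray
    space: LabelSpace

    def __post_init__(self):
        v = np.asarray(self.v, dtype=np.int64)
        if v.shape != (self.space.C,) or (v < 0).any():
            raise ValidationError("v must be a length-C nonnegative vector")
        if v.sum() < 1:
            raise ValidationError("prediction counts are empty (N = 0)")
        object.__setattr__(self, "v", v)

    @property
    def N(self) -> int:
        return int(self.v.sum())

    @property
    def naive_q(self) -> np.ndarray:
        """The uncalibrated plug-in estimate ``v / N``."""
        return self.v / self.N


@dataclass(frozen=True)
class TransferCounts:
    """C×C counts ``t_ij`` of (true i, predicted j) pairs on the labeled set."""

    T: np.ndarray
    space: LabelSpace

    def __post_init__(self):
        T = np.asarray(self.T, dtype=np.int64)
        C = self.space.C
        if T.shape != (C, C) or (T < 0).any():
            raise ValidationError("T must be a C×C nonnegative matrix")
        object.__setattr__(self, "T", T)

    @property
    def n_i(self) -> np.ndarray:
        """Labeled sample size per true class (row sums)."""
        return self.T.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.T.sum())


@dataclass(frozen=True)
class Hyperparams:
    """Prior hyperparameters.

    epsilon
        Small positive constant in the Dirichlet prior
        ``M_i* ~ Dirichlet(gamma_i (e_i + epsilon 1))``; keeps the posterior
        proper when off-diagonal transfer counts are zero.  The shrinkage
        theorems hold in the limit ``epsilon -> 0``.
    delta
        Concentration of the ``Dirichlet(delta 1)`` prior on ``p``.  ``0`` is
        allowed as an improper theorem-limit mode.
    alpha, beta
        Shape/rate of the Gamma prior on each shrinkage scale ``gamma_i``.
    """

    epsilon: float = 1e-3
    delta: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValidationError("epsilon must be > 0")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValidationError("alpha and beta must be > 0")
        if self.delta == 0:
            warnings.warn(
                "delta = 0 uses an improper prior on p (theorem-limit mode); "
                "the posterior is proper only if every class is reachable",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class SamplerControl:
    """MCMC run controls (chains, length, Metropolis tuning, seed)."""

    n_chains: int = 3
    n_iter: int = 5000
    n_burnin: int | None = None
    thin: int = 1
    seed: int = 0
    mh_step: float = 0.5
    adapt: bool = True
    store_b: bool = False

    def __post_init__(self):
        burn = self.n_iter // 2 if self.n_burnin is None else self.n_burnin
        object.__setattr__(self, "n_burnin", int(burn))
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValidationError("need 0 <= n_burnin < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValidationError("thin and n_chains must be >= 1")
        if not self.mh_step > 0:
            raise ValidationError("mh_step must be > 0")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Stored MCMC draws for one calibration run.

    Shapes: ``p`` is (chains, draws, C); ``M`` is (chains, draws, K, C, C);
    ``gamma`` is (chains, draws, K, C); ``accept`` is the per-chain
    Metropolis acceptance rate for each gamma, shape (chains, K, C).  For the
    single-classifier model K = 1.
    """

    p: np.ndarray
    M: np.ndarray
    gamma: np.ndarray
    accept: np.ndarray
    space: LabelSpace
    hyper: Hyperparams
    control: SamplerControl
    b: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.M.shape[2]

    @property
    def p_mean(self) -> np.ndarray:
        return self.p.mean(axis=(0, 1))

    @property
    def M_mean(self) -> np.ndarray:
        """Posterior mean confusion matrix; (C, C) for K = 1 else (K, C, C)."""
        m = self.M.mean(axis=(0, 1))
        return m[0] if m.shape[0] == 1 else m

    def to_param_dict(self) -> dict[str, np.ndarray]:
        """Chain-major arrays keyed by parameter name, for summarization."""
        out = {"p": self.p}
        if self.n_channels == 1:
            out["M"] = self.M[:, :, 0]
            out["gamma"] = self.gamma[:, :, 0]
        else:
            out["M"] = self.M
            out["gamma"] = self.gamma
        return out


# ---------------------------------------------------------------------------
# tabulation and moment estimators
# ---------------------------------------------------------------------------


def check_confusion(M: np.ndarray) -> np.ndarray:
    """Validate a row-stochastic confusion matrix and return it as float."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if (M < -_SIMPLEX_TOL).any() or (M > 1 + _SIMPLEX_TOL).any():
        raise ValidationError("confusion matrix entries must lie in [0, 1]")
    if np.abs(M.sum(axis=1) - 1.0).max() > _SIMPLEX_TOL:
        raise ValidationError("confusion matrix rows must sum to 1")
    return M


def check_csmf(p: np.ndarray) -> np.ndarray:
    """Validate a probability vector on the C-simplex."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or (p < -_SIMPLEX_TOL).any():
        raise ValidationError("CSMF must be a nonnegative vector")
    if abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValidationError(f"CSMF must sum to 1 (got {p.sum()!r})")
    return p


def tabulate_predictions(labels: Sequence[str], space: LabelSpace) -> PredictionCounts:
    """Count predicted classes on the unlabeled set (``v_i`` of the model)."""
    if len(labels) == 0:
        raise ValidationError("empty prediction set")
    codes = space.codes(labels)
    v = np.bincount(codes, minlength=space.C)
    return PredictionCounts(v=v, space=space)


def tabulate_transfer(
    true_labels: Sequence[str], pred_labels: Sequence[str], space: LabelSpace
) -> TransferCounts:
    """Cross-tabulate (true, predicted) pairs from the labeled set into T."""
    if len(true_labels) != len(pred_labels):
        raise ValidationError(
            f"length mismatch: {len(true_labels)} true vs {len(pred_labels)} predicted"
        )
    C = space.C
    if len(true_labels) == 0:
        return TransferCounts(T=np.zeros((C, C), dtype=np.int64), space=space)
    g = space.codes(true_labels)
    a = space.codes(pred_labels)
    T = np.bincount(g * C + a, minlength=C * C).reshape(C, C)
    return TransferCounts(T=T, space=space)


def mom_confusion(T: TransferCounts) -> np.ndarray:
    """Method-of-moments estimate ``m_ij = t_ij / n_i`` (requires n_i > 0)."""
    n_i = T.n_i
    if (n_i == 0).any():
        empty = [T.space.classes[i] for i in np.flatnonzero(n_i == 0)]
        raise ValidationError(
            f"no labeled records for class(es) {empty}; the method-of-moments "
            "estimate is undefined — use shrink_confusion instead"
        )
    return T.T / n_i[:, None]


def shrink_confusion(T: TransferCounts, gamma: float | np.ndarray) -> np.ndarray:
    """Row-wise shrinkage of the empirical confusion matrix toward identity.

    Row i is ``(1 - lambda_i) T_i*/n_i + lambda_i e_i`` with
    ``lambda_i = gamma_i / (n_i + gamma_i)``; a row with no labeled data
    (``n_i = 0``) is exactly the identity row (``lambda_i = 1``).
    """
    return _shrink_rows(T.T, gamma)


def _shrink_rows(T: np.ndarray, gamma: float | np.ndarray) -> np.ndarray:
    C = T.shape[0]
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (C,))
    if (gamma <= 0).any():
        raise ValidationError("gamma must be positive")
    n_i = T.sum(axis=1)
    lam = gamma / (n_i + gamma)
    M = np.eye(C) * lam[:, None]
    pos = n_i > 0
    M[pos] += (1 - lam[pos, None]) * T[pos] / n_i[pos, None]
    return M


def compose_q(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Marginal predicted-class distribution ``q = M' p``."""
    M = check_confusion(M)
    p = check_csmf(p)
    if M.shape[0] != p.shape[0]:
        raise ValidationError("M and p dimensions do not match")
    return M.T @ p


def individual_posterior(M: np.ndarray, p: np.ndarray, j: int) -> np.ndarray:
    """Posterior class probabilities for one record predicted as class j.

    By Bayes' rule ``P(G = i | A = j) = m_ij p_i / sum_i m_ij p_i``.  Applied
    per posterior draw of (M, p) and averaged, this gives model-based
    individual-level class probabilities.
    """
    M = check_confusion(M)
    p = check_csmf(p)
    w = M[:, j] * p
    s = w.sum()
    if s <= 0:
        raise ValidationError(
            f"predicted class {j} has zero probability under (M, p); "
            "individual posterior undefined"
        )
    return w / s


# ---------------------------------------------------------------------------
# gamma full conditional and the Gibbs sampler
# ---------------------------------------------------------------------------


def log_gamma_conditional(
    gamma: float, m_row: np.ndarray, diag_index: int, hyper: Hyperparams
) -> float:
    """Unnormalized log full-conditional density of one shrinkage scale.

    Given the current confusion-matrix row, the density is

        Gamma(C g e + g) / [Gamma(g e)^(C-1) Gamma(g e + g)]
        * g^(alpha-1) exp(-beta g) * prod_j m_ij^(g e + g 1(i=j))

    evaluated in log space with ``gammaln`` throughout.
    """
    if not gamma > 0:
        raise ValidationError("gamma must be positive")
    m_row = np.asarray(m_row, dtype=float)
    if (m_row <= 0).any():
        raise ValidationError("m_row must be strictly positive")
    C = m_row.shape[0]
    g, e = float(gamma), hyper.epsilon
    logm = np.log(m_row)
    val = (
        gammaln(C * g * e + g)
        - (C - 1) * gammaln(g * e)
        - gammaln(g * e + g)
        + (hyper.alpha - 1) * math.log(g)
        - hyper.beta * g
        + g * e * logm.sum()
        + g * logm[diag_index]
    )
    return float(val)


def _init_p(v_stack: np.ndarray) -> np.ndarray:
    """Initial p: pooled naive estimate, floored at 1/(10C) and renormalized."""
    K, C = v_stack.shape
    p0 = (v_stack / v_stack.sum(axis=1, keepdims=True)).mean(axis=0)
    p0 = np.maximum(p0, 1.0 / (10 * C))
    return p0 / p0.sum()


def _dirichlet_p_alpha(row_sums: np.ndarray, delta: float) -> np.ndarray:
    alpha = row_sums + delta
    # delta = 0 theorem-limit mode: numpy requires strictly positive alpha
    return np.maximum(alpha, 1e-12)


def _run_chain(
    seed_seq: np.random.SeedSequence,
    v: np.ndarray,
    T: np.ndarray,
    hyper: Hyperparams,
    control: SamplerControl,
):
    """One MCMC chain of the shared K-channel sampler.

    Sweep order (fixed): latent allocations B, confusion rows M, CSMF p,
    shrinkage scales gamma.  Returns kept draws and gamma acceptance rates.
    """
    rng = np.random.default_rng(seed_seq)
    K, C = v.shape
    eps, delta = hyper.epsilon, hyper.delta

    p = _init_p(v)
    gamma = np.ones((K, C))
    M = np.stack([_shrink_rows(T[k], gamma[k]) for k in range(K)])
    M = np.clip(M, _LOG_FLOOR, None)

    step = np.full((K, C), control.mh_step)
    n_kept = control.n_kept
    keep_p = np.empty((n_kept, C))
    keep_M = np.empty((n_kept, K, C, C))
    keep_g = np.empty((n_kept, K, C))
    keep_b = np.empty((n_kept, K, C, C)) if control.store_b else None
    acc = np.zeros((K, C))
    n_acc_iters = 0
    adapt_acc = np.zeros((K, C))
    adapt_window = 50

    B = np.zeros((K, C, C))
    kept = 0
    for it in range(control.n_iter):
        # --- latent allocation of each predicted-class total to true classes
        B[:] = 0
        for k in range(K):
            for j in range(C):
                vj = v[k, j]
                if vj == 0:
                    continue
                w = M[k, :, j] * p
                s = w.sum()
                if not s > 0:
                    raise SamplerError(
                        f"all-zero allocation weights (channel {k}, class {j}, "
                        f"iteration {it}); check epsilon configuration"
                    )
                B[k, :, j] = rng.multinomial(vj, w / s)

        # --- conjugate confusion-row updates
        for k in range(K):
            for i in range(C):
                a = B[k, i] + T[k, i] + gamma[k, i] * eps
                a[i] += gamma[k, i]
                M[k, i] = np.clip(rng.dirichlet(a), _LOG_FLOOR, None)

        # --- conjugate CSMF update (latent true-class totals pooled over channels)
        p = rng.dirichlet(_dirichlet_p_alpha(B.sum(axis=(0, 2)), delta))
        p = np.clip(p, _LOG_FLOOR, None)

        # --- Metropolis on log gamma (log-normal random walk, Jacobian included)
        for k in range(K):
            for i in range(C):
                cur = gamma[k, i]
                l_cur = log_gamma_conditional(cur, M[k, i], i, hyper)
                prop = math.exp(math.log(cur) + step[k, i] * rng.standard_normal())
                l_prop = log_gamma_conditional(prop, M[k, i], i, hyper)
                if not (math.isfinite(l_prop) or math.isfinite(l_cur)):
                    raise SamplerError(
                        "non-finite gamma log-density; check epsilon configuration"
                    )
                log_ratio = l_prop - l_cur + math.log(prop) - math.log(cur)
                if math.log(rng.uniform()) < log_ratio:
                    gamma[k, i] = prop
                    adapt_acc[k, i] += 1
                    if it >= control.n_burnin:
                        acc[k, i] += 1

        # Robbins-Monro-style scale adaptation during burn-in, targeting ~35%
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
                if keep_b is not None:
                    keep_b[kept] = B
                kept += 1

    acc_rate = acc / max(n_acc_iters, 1)
    return keep_p[:kept], keep_M[:kept], keep_g[:kept], (
        keep_b[:kept] if keep_b is not None else None
    ), acc_rate


def run_channel_sampler(
    vs: Sequence[PredictionCounts],
    Ts: Sequence[TransferCounts],
    hyper: Hyperparams | None = None,
    control: SamplerControl | None = None,
) -> PosteriorDraws:
    """Shared K-channel Gibbs sampler behind the single and independent-ensemble models."""
    hyper = hyper or Hyperparams()
    control = control or SamplerControl()
    if len(vs) != len(Ts) or len(vs) == 0:
        raise ValidationError("need matching nonempty lists of counts")
    space = vs[0].space
    for obj in (*vs, *Ts):
        if obj.space.classes != space.classes:
            raise ValidationError("all inputs must share one label space")
    n_rows = {tuple(t.n_i) for t in Ts}
    if len(n_rows) > 1:
        raise ValidationError(
            "transfer matrices must come from the same labeled records "
            "(row sums differ across classifiers)"
        )
    v = np.stack([pc.v for pc in vs])
    T = np.stack([tc.T for tc in Ts])

    seeds = np.random.SeedSequence(control.seed).spawn(control.n_chains)
    chains = [_run_chain(s, v, T, hyper, control) for s in seeds]
    return PosteriorDraws(
        p=np.stack([c[0] for c in chains]),
        M=np.stack([c[1] for c in chains]),
        gamma=np.stack([c[2] for c in chains]),
        b=(np.stack([c[3] for c in chains]) if control.store_b else None),
        accept=np.stack([c[4] for c in chains]),
        space=space,
        hyper=hyper,
        control=control,
    )


def gibbs_single(
    v: PredictionCounts,
    T: TransferCounts,
    hyper: Hyperparams | None = None,
    control: SamplerControl | None = None,
) -> PosteriorDraws:
    """Fit the single-classifier calibration model by augmented-data Gibbs sampling.

    Per sweep: latent columns ``b_j ~ Multinomial(v_j, (m_1j p_1, ..., m_Cj p_C)
    / sum_i m_ij p_i)``; confusion rows ``M_i* ~ Dirichlet(b_i* + gamma_i eps 1
    + T_i* + gamma_i e_i)``; ``p ~ Dirichlet(rowsums(B) + delta)``; each
    ``gamma_i`` by log-normal random-walk Metropolis.
    """
    return run_channel_sampler([v], [T], hyper, control)
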