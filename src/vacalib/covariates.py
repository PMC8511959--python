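"""Covariate-dependent CSMF calibration.

Replaces the Dirichlet prior on the CSMF with a multinomial-logistic
regression on record-level covariates: pattern h has class probabilities

    p_hi = exp(x_h' beta_i) / sum_i exp(x_h' beta_i),   beta_C = 0,

with independent Gaussian priors on the coefficient vectors beta_i.  The
confusion-matrix part of the model, the latent-count augmentation and the
shrinkage-scale updates are unchanged; the coefficient block is sampled
conjugately after Polya-Gamma augmentation of the multinomial-logistic
likelihood (one PG variable per pattern and non-reference class).

Population-level (marginal) CSMFs are recovered by averaging the
pattern-specific vectors over the empirical covariate distribution of the
unlabeled records: p_i = sum_h (n_h / N) p_hi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp

from ._polya_gamma import random_polyagamma
from .model_core import (
    Hyperparams,
    LabelSpace,
    SamplerControl,
    SamplerError,
    TransferCounts,
    ValidationError,
    _LOG_FLOOR,
    _shrink_rows,
    log_gamma_conditional,
)

__all__ = [
    "CovariateDesign",
    "CoefficientPrior",
    "CovariatePosterior",
    "build_design",
    "softmax_csmf",
    "gibbs_covariate",
    "marginal_csmf",
]


@dataclass(frozen=True)
class CovariateDesign:
    """Design over the H unique covariate patterns of the unlabeled set.

    ``X`` is the H×d design matrix (intercept included); ``V`` the H×C matrix
    of predicted-class counts per pattern; ``n_h`` the per-pattern record
    counts (row sums of V).
    """

    X: np.ndarray
    V: np.ndarray
    space: LabelSpace
    columns: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        V = np.asarray(self.V, dtype=np.int64)
        if X.ndim != 2 or V.shape != (X.shape[0], self.space.C):
            raise ValidationError("X must be H×d and V H×C with matching H")
        if (V < 0).any() or V.sum() < 1:
            raise ValidationError("V must be nonnegative with at least one record")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "V", V)

    @property
    def H(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_h(self) -> np.ndarray:
        return self.V.sum(axis=1)

    @property
    def N(self) -> int:
        return int(self.V.sum())


@dataclass(frozen=True)
class CoefficientPrior:
    """Independent N(m0, W0) priors for the non-reference coefficient vectors."""

    m0: np.ndarray  # (d, C-1)
    W0: np.ndarray  # (C-1, d, d), each SPD

    @classmethod
    def default(cls, d: int, C: int, scale: float = 25.0) -> "CoefficientPrior":
        """Weakly informative default: zero mean, variance ``scale`` per coefficient."""
        return cls(
            m0=np.zeros((d, C - 1)),
            W0=np.tile(scale * np.eye(d), (C - 1, 1, 1)),
        )

    def __post_init__(self):
        m0 = np.asarray(self.m0, dtype=float)
        W0 = np.asarray(self.W0, dtype=float)
        if W0.shape != (m0.shape[1], m0.shape[0], m0.shape[0]):
            raise ValidationError("prior shapes inconsistent: m0 (d, C-1), W0 (C-1, d, d)")
        for i, W in enumerate(W0):
            if not np.allclose(W, W.T):
                raise ValidationError(f"W0[{i}] is not symmetric")
            if np.linalg.eigvalsh(W).min() <= 0:
                raise ValidationError(f"W0[{i}] is not positive definite")
        object.__setattr__(self, "m0", m0)
        object.__setattr__(self, "W0", W0)


def build_design(
    records: pd.DataFrame,
    covariates: Sequence[tuple[str, str]],
    space: LabelSpace,
    predicted_col: str = "predicted",
) -> CovariateDesign:
    """Build the pattern-level design from record-level covariates and predictions.

    ``covariates`` lists (column name, kind) with kind ``"categorical"`` or
    ``"continuous"``.  When all covariates are categorical, records are
    deduplicated into H unique patterns; any continuous covariate forces one
    pattern per record (H = N).  Categorical covariates are dummy-coded with
    the first level as reference; an intercept column is always included.
    Missing covariate values are rejected — no imputation.
    """
    if predicted_col not in records.columns:
        raise ValidationError(f"missing column {predicted_col!r}")
    names = [name for name, _ in covariates]
    for name, kind in covariates:
        if name not in records.columns:
            raise ValidationError(f"missing covariate column {name!r}")
        if kind not in ("categorical", "continuous"):
            raise ValidationError(f"unknown covariate kind {kind!r} for {name!r}")
        if records[name].isna().any():
            raise ValidationError(f"missing values in covariate {name!r}")
    codes = space.codes(records[predicted_col].tolist())

    all_categorical = all(kind == "categorical" for _, kind in covariates)
    df = records[names].copy() if names else pd.DataFrame(index=records.index)
    if all_categorical and names:
        key = df.astype(str).agg("\x1f".join, axis=1)
        patterns, pattern_idx = np.unique(key.to_numpy(), return_inverse=True)
        rep_rows = pd.Series(np.arange(len(key)), index=None).groupby(pattern_idx).first()
        pattern_df = df.iloc[rep_rows.to_numpy()].reset_index(drop=True)
    elif not names:  # intercept-only
        pattern_idx = np.zeros(len(records), dtype=np.intp)
        pattern_df = pd.DataFrame(index=[0])
    else:
        if len(records) > 5000:
            warnings.warn(
                f"continuous covariates give one pattern per record (H = {len(records)}); "
                "sampling may be slow",
                UserWarning,
                stacklevel=2,
            )
        pattern_idx = np.arange(len(records), dtype=np.intp)
        pattern_df = df.reset_index(drop=True)

    H = len(pattern_df)
    cols: list[np.ndarray] = [np.ones(H)]
    col_names = ["intercept"]
    for name, kind in covariates:
        if kind == "continuous":
            cols.append(pattern_df[name].to_numpy(dtype=float))
            col_names.append(name)
        else:
            levels = sorted(pd.unique(records[name].astype(str)))
            for lev in levels[1:]:  # first level is the reference
                cols.append((pattern_df[name].astype(str) == lev).to_numpy(dtype=float))
                col_names.append(f"{name}[{lev}]")
    X = np.column_stack(cols)

    V = np.zeros((H, space.C), dtype=np.int64)
    np.add.at(V, (pattern_idx, codes), 1)
    return CovariateDesign(X=X, V=V, space=space, columns=tuple(col_names))


def softmax_csmf(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pattern-level CSMFs from coefficients: row-wise softmax of X beta.

    ``beta`` is d×(C-1); the reference (last) class has coefficients fixed at
    zero.  Computed with max-subtraction for overflow safety.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    eta = X @ np.column_stack([beta, np.zeros(beta.shape[0])])
    if not np.isfinite(eta).all():
        raise ValidationError("non-finite linear predictor")
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def marginal_csmf(p_h: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Population CSMF as the weight-averaged pattern CSMFs, p_i = sum_h (n_h/N) p_hi."""
    p_h = np.asarray(p_h, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("weights must be nonnegative with positive total")
    return (p_h * (w / w.sum())[:, None]).sum(axis=0)


@dataclass
class CovariatePosterior:
    """Draws from the covariate model: coefficients, confusion matrix, scales."""

    beta: np.ndarray  # (chains, draws, d, C-1)
    M: np.ndarray  # (chains, draws, C, C)
    gamma: np.ndarray  # (chains, draws, C)
    accept: np.ndarray
    design: CovariateDesign
    hyper: Hyperparams
    control: SamplerControl

    def pattern_csmf_draws(self) -> np.ndarray:
        """Derived p_h per draw; shape (chains, draws, H, C)."""
        ch, dr = self.beta.shape[:2]
        out = np.empty((ch, dr, self.design.H, self.design.space.C))
        for c in range(ch):
            for t in range(dr):
                out[c, t] = softmax_csmf(self.beta[c, t], self.design.X)
        return out

    def marginal_csmf_draws(self) -> np.ndarray:
        """Marginal CSMF per draw, weighted by pattern record counts."""
        p_h = self.pattern_csmf_draws()
        w = self.design.n_h / self.design.N
        return (p_h * w[None, None, :, None]).sum(axis=2)

    @property
    def marginal_csmf_mean(self) -> np.ndarray:
        return self.marginal_csmf_draws().mean(axis=(0, 1))


def _run_covariate_chain(seed_seq, design, T, prior, hyper, control):
    rng = np.random.default_rng(seed_seq)
    X, V = design.X, design.V
    H, d = X.shape
    C = design.space.C
    n_h = design.n_h.astype(float)
    eps = hyper.epsilon

    W0inv = np.stack([np.linalg.inv(W) for W in prior.W0])
    W0inv_m0 = np.stack([W0inv[i] @ prior.m0[:, i] for i in range(C - 1)])

    beta = np.zeros((d, C - 1))
    gamma = np.ones(C)
    M = np.clip(_shrink_rows(T, gamma), _LOG_FLOOR, None)
    step = np.full(C, control.mh_step)

    n_kept = control.n_kept
    keep_beta = np.empty((n_kept, d, C - 1))
    keep_M = np.empty((n_kept, C, C))
    keep_g = np.empty((n_kept, C))
    acc = np.zeros(C)
    adapt_acc = np.zeros(C)
    adapt_window = 50
    n_acc_iters = 0
    kept = 0

    for it in range(control.n_iter):
        p_h = softmax_csmf(beta, X)  # (H, C)

        # latent allocation per (pattern, predicted class); S[h, i] = sum_j b_hij
        S = np.zeros((H, C))
        A = np.zeros((C, C))  # sum over h of b_hij, for the M update
        for h in range(H):
            for j in range(C):
                vhj = V[h, j]
                if vhj == 0:
                    continue
                w = M[:, j] * p_h[h]
                s = w.sum()
                if not s > 0:
                    raise SamplerError(
                        f"all-zero allocation weights (pattern {h}, class {j})"
                    )
                b = rng.multinomial(vhj, w / s)
                S[h] += b
                A[:, j] += b

        # conjugate confusion-row updates (epsilon form of the Dirichlet prior)
        for i in range(C):
            a = A[i] + T[i] + gamma[i] * eps
            a[i] += gamma[i]
            M[i] = np.clip(rng.dirichlet(a), _LOG_FLOOR, None)

        # Polya-Gamma block: one (omega, beta_i) update per non-reference class
        for i in range(C - 1):
            eta = X @ np.column_stack([beta, np.zeros(d)])  # (H, C)
            others = np.delete(eta, i, axis=1)
            c_i = logsumexp(others, axis=1)
            z = eta[:, i] - c_i
            omega = random_polyagamma(rng, n_h, z)
            kappa = S[:, i] - n_h / 2.0
            Winv = X.T @ (omega[:, None] * X) + W0inv[i]
            try:
                cf = cho_factor(Winv)
            except np.linalg.LinAlgError as exc:
                raise SamplerError(
                    f"singular precision for class {i}: collinear design?"
                ) from exc
            # linear term X'(kappa + Omega c): expanding kappa*psi - omega*psi^2/2
            # with psi = x'beta - c gives coefficient (kappa + omega c) on x'beta
            rhs = X.T @ (kappa + omega * c_i) + W0inv_m0[i]
            mean = cho_solve(cf, rhs)
            # draw N(mean, Winv^{-1}): with Winv = U'U, solve U u = z
            u = solve_triangular(cf[0], rng.standard_normal(d), lower=cf[1])
            beta[:, i] = mean + u

        for i in range(C):
            cur = gamma[i]
            l_cur = log_gamma_conditional(cur, M[i], i, hyper)
            prop = math.exp(math.log(cur) + step[i] * rng.standard_normal())
            l_prop = log_gamma_conditional(prop, M[i], i, hyper)
            if math.log(rng.uniform()) < l_prop - l_cur + math.log(prop) - math.log(cur):
                gamma[i] = prop
                adapt_acc[i] += 1
                if it >= control.n_burnin:
                    acc[i] += 1

        if control.adapt and it < control.n_burnin and (it + 1) % adapt_window == 0:
            step *= np.exp((adapt_acc / adapt_window - 0.35) / math.sqrt((it + 1) / adapt_window))
            adapt_acc[:] = 0
        if it >= control.n_burnin:
            n_acc_iters += 1
            if (it - control.n_burnin) % control.thin == 0:
                keep_beta[kept] = beta
                keep_M[kept] = M
                keep_g[kept] = gamma
                kept += 1

    return keep_beta[:kept], keep_M[:kept], keep_g[:kept], acc / max(n_acc_iters, 1)


def gibbs_covariate(
    design: CovariateDesign,
    T: TransferCounts,
    prior: CoefficientPrior | None = None,
    hyper: Hyperparams | None = None,
    control: SamplerControl | None = None,
) -> CovariatePosterior:
    """Fit the covariate-dependent calibration model.

    Per sweep: latent counts ``b_hj ~ Multinomial(v_hj, weights ∝ m_ij p_hi)``;
    confusion rows conjugate as in the marginal model; for each non-reference
    class, ``omega_hi ~ PG(n_h, x_h' beta_i - c_hi)`` with
    ``c_hi = log sum_{k != i} exp(x_h' beta_k)``, then a conjugate Gaussian
    coefficient draw with precision ``X' Omega_i X + W0_i^{-1}`` and
    ``kappa_hi = sum_j b_hij - n_h / 2``; shrinkage scales by Metropolis.
    """
    hyper = hyper or Hyperparams()
    control = control or SamplerControl()
    if T.space.classes != design.space.classes:
        raise ValidationError("design and transfer counts must share one label space")
    prior = prior or CoefficientPrior.default(design.d, design.space.C)
    if prior.m0.shape != (design.d, design.space.C - 1):
        raise ValidationError("prior dimensions do not match the design")

    seeds = np.random.SeedSequence(control.seed).spawn(control.n_chains)
    chains = [
        _run_covariate_chain(s, design, T.T, prior, hyper, control) for s in seeds
    ]
    return CovariatePosterior(
        beta=np.stack([c[0] for c in chains]),
        M=np.stack([c[1] for c in chains]),
        gamma=np.stack([c[2] for c in chains]),
        accept=np.stack([c[3] for c in chains]),
        design=design,
        hyper=hyper,
        control=control,
    )
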