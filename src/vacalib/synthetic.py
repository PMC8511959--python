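"""Synthetic-data harness emulating classifier channels over a 4-cause label space.

Real computer-coded verbal-autopsy classifiers enter the calibration model
only through their confusion matrices: given the true cause, a prediction is
a draw from the corresponding confusion-matrix row, and predictions from
different classifiers are conditionally independent given the truth.  The
generator therefore simulates classifier *channels* directly from
row-stochastic matrices, which exercises every sampler in the package
without any external classifier software.

Built-in channels (C = 4, causes Pneumonia, Diarrhea/Dysentery, Sepsis,
Other):

* ``M1`` — the identity: a perfect classifier.
* ``M2`` — two systematic biases: 65% of Diarrhea/Dysentery deaths are
  predicted Pneumonia, 50% of Sepsis deaths are predicted Other.
* ``M3`` — many small errors: 0.6 I + 0.1 (all-ones), i.e. 70% on the
  diagonal and 10% on each off-diagonal.

Study conditions mirror a simulation design in which the labeled-set and
population CSMFs (p_L, p_U) are independent Dirichlet(1) draws binned by
their CSMF accuracy into low (< 0.4), medium (0.4–0.6) and high (> 0.6)
disparity scenarios, with labeled sizes n in {50, 100, 200, 400} and a large
unlabeled set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import ensemble as ens
from .metrics import csmfa
from .model_core import (
    Hyperparams,
    LabelSpace,
    PredictionCounts,
    SamplerControl,
    TransferCounts,
    ValidationError,
    check_confusion,
    check_csmf,
    compose_q,
    gibbs_single,
    individual_posterior,
    tabulate_transfer,
)

__all__ = [
    "DEFAULT_CLASSES",
    "ScenarioSpec",
    "SyntheticDataset",
    "builtin_confusion",
    "scenario_of",
    "sample_csmf_pair",
    "generate_dataset",
    "run_study",
]

DEFAULT_CLASSES = ("Pneumonia", "Diarrhea/Dysentery", "Sepsis", "Other")

_SCENARIO_BINS = {"low": (0.0, 0.4), "medium": (0.4, 0.6), "high": (0.6, 1.0)}

_M2 = np.array(
    [
        [1.00, 0.00, 0.00, 0.00],
        [0.65, 0.35, 0.00, 0.00],
        [0.00, 0.00, 0.50, 0.50],
        [0.00, 0.00, 0.00, 1.00],
    ]
)


def builtin_confusion(name: str, C: int = 4) -> np.ndarray:
    """Return one of the built-in confusion channels M1, M2, M3."""
    if name == "M1":
        return np.eye(C)
    if name == "M2":
        if C != 4:
            raise ValidationError("M2 is defined for C = 4 only")
        return _M2.copy()
    if name == "M3":
        return 0.6 * np.eye(C) + 0.1 * np.ones((C, C))
    raise ValidationError(f"unknown confusion matrix {name!r}; choose M1, M2 or M3")


def scenario_of(a: float) -> str:
    """Scenario bin of a CSMFA value; boundary values fall in the lower bin."""
    if a <= 0.4:
        return "low"
    if a <= 0.6:
        return "medium"
    return "high"


def sample_csmf_pair(
    scenario: str,
    C: int = 4,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Rejection-sample a (p_L, p_U) pair of Dirichlet(1) vectors into a scenario bin.

    Returns the accepted pair and the number of attempts used.
    """
    if scenario not in _SCENARIO_BINS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(rng)
    for attempt in range(1, max_attempts + 1):
        p_L = rng.dirichlet(np.ones(C))
        p_U = rng.dirichlet(np.ones(C))
        if scenario_of(csmfa(p_L, p_U)) == scenario:
            return p_L, p_U, attempt
    raise RuntimeError(
        f"no pair fell in scenario {scenario!r} within {max_attempts} attempts"
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell: scenario bin, sizes, and classifier channels."""

    scenario: str = "low"
    C: int = 4
    N: int = 5000
    n: int = 400
    Ms: tuple = ("M2",)
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIO_BINS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.N < 1 or self.n < 0:
            raise ValidationError("need N >= 1 and n >= 0")
        Ms = tuple(
            builtin_confusion(m, self.C) if isinstance(m, str) else check_confusion(m)
            for m in self.Ms
        )
        for M in Ms:
            if M.shape != (self.C, self.C):
                raise ValidationError("confusion matrix dimension mismatch")
        object.__setattr__(self, "Ms", Ms)


@dataclass
class SyntheticDataset:
    """Simulated records: predictions, held-out truth, and generating parameters."""

    space: LabelSpace
    unlabeled_pred: np.ndarray  # (N, K) int codes
    unlabeled_true: np.ndarray  # (N,) int codes, held out for scoring
    labeled_pred: np.ndarray  # (n, K) int codes
    labeled_true: np.ndarray  # (n,) int codes
    p_U: np.ndarray
    p_L: np.ndarray
    Ms: tuple

    @property
    def K(self) -> int:
        return self.unlabeled_pred.shape[1]

    def prediction_counts(self, k: int = 0) -> PredictionCounts:
        v = np.bincount(self.unlabeled_pred[:, k], minlength=self.space.C)
        return PredictionCounts(v=v, space=self.space)

    def transfer_counts(self, k: int = 0) -> TransferCounts:
        names = np.asarray(self.space.classes)
        return tabulate_transfer(
            names[self.labeled_true], names[self.labeled_pred[:, k]], self.space
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(unlabeled, labeled) tables in the delimited-input schema."""
        names = np.asarray(self.space.classes)
        K = self.K
        pred_cols = (
            {"predicted": names[self.unlabeled_pred[:, 0]]}
            if K == 1
            else {
                f"predicted_{k + 1}": names[self.unlabeled_pred[:, k]]
                for k in range(K)
            }
        )
        unl = pd.DataFrame({"id": np.arange(len(self.unlabeled_true)), **pred_cols})
        lab_pred = (
            {"predicted": names[self.labeled_pred[:, 0]]}
            if K == 1
            else {
                f"predicted_{k + 1}": names[self.labeled_pred[:, k]] for k in range(K)
            }
        )
        lab = pd.DataFrame(
            {
                "id": np.arange(len(self.labeled_true)),
                "true": names[self.labeled_true],
                **lab_pred,
            }
        )
        return unl, lab


def _draw_a_then_g(rng, M, p, size):
    """Single-channel generation: A ~ q = M'p, then G | A = j from the Bayes rule."""
    q = compose_q(M, p)
    a = rng.choice(len(p), size=size, p=q)
    g = np.empty(size, dtype=np.intp)
    for j in np.unique(a):
        alpha_j = individual_posterior(M, p, int(j))
        idx = np.flatnonzero(a == j)
        g[idx] = rng.choice(len(p), size=idx.size, p=alpha_j)
    return a, g


def _draw_g_then_a(rng, Ms, p, size):
    """Multi-channel generation: G ~ p, then each A^(k) | G from the M^(k) row."""
    g = rng.choice(len(p), size=size, p=p)
    A = np.empty((size, len(Ms)), dtype=np.intp)
    for k, M in enumerate(Ms):
        for i in np.unique(g):
            idx = np.flatnonzero(g == i)
            A[idx, k] = rng.choice(len(p), size=idx.size, p=M[i])
    return A, g


def generate_dataset(
    spec: ScenarioSpec,
    p_U: np.ndarray | None = None,
    p_L: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Simulate one dataset from the channel model.

    If the CSMF pair is not supplied it is rejection-sampled into the
    scenario bin.  For a single channel, records are generated
    prediction-first (A from the marginal q = M'p, then the truth from the
    Bayes-rule class probabilities given A); for multiple channels,
    truth-first with conditionally independent predictions.  Both orders
    define the same joint law.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if (p_U is None) != (p_L is None):
        raise ValidationError("supply both of p_U and p_L, or neither")
    if p_U is None:
        p_L, p_U, _ = sample_csmf_pair(spec.scenario, spec.C, rng)
    else:
        p_U, p_L = check_csmf(p_U), check_csmf(p_L)

    K = len(spec.Ms)
    if K == 1:
        a_u, g_u = _draw_a_then_g(rng, spec.Ms[0], p_U, spec.N)
        A_u = a_u[:, None]
        a_l, g_l = _draw_a_then_g(rng, spec.Ms[0], p_L, spec.n)
        A_l = a_l[:, None]
    else:
        A_u, g_u = _draw_g_then_a(rng, spec.Ms, p_U, spec.N)
        A_l, g_l = _draw_g_then_a(rng, spec.Ms, p_L, spec.n)

    space = LabelSpace(
        DEFAULT_CLASSES if spec.C == 4 else tuple(f"cause_{i + 1}" for i in range(spec.C))
    )
    return SyntheticDataset(
        space=space,
        unlabeled_pred=A_u,
        unlabeled_true=g_u,
        labeled_pred=A_l,
        labeled_true=g_l,
        p_U=p_U,
        p_L=p_L,
        Ms=spec.Ms,
    )


_DEFAULT_ESTIMATORS = ("naive", "calibrated", "ensemble_independent")


def run_study(
    scenarios: Sequence[str] = ("low", "medium", "high"),
    M_names: Sequence[str] = ("M1", "M2", "M3"),
    n_values: Sequence[int] = (50, 100, 200, 400),
    replicates: int = 20,
    N: int = 5000,
    estimators: Sequence[str] = _DEFAULT_ESTIMATORS,
    hyper: Hyperparams | None = None,
    control: SamplerControl | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the simulation grid and score every estimator by CSMF accuracy.

    Each cell pairs the cell's confusion channel with a fixed companion
    channel (M3, or M2 when the cell itself is M3) so the ensemble
    estimators always combine two classifiers of different quality.
    ``calibrated`` rows are emitted once per channel (``classifier`` column
    1 or 2); ``naive`` likewise.  Estimator failures are recorded in the
    ``error`` column rather than aborting the grid.
    """
    hyper = hyper or Hyperparams()
    control = control or SamplerControl(n_chains=1, n_iter=1000, n_burnin=500, seed=0)
    estimators = tuple(estimators)
    unknown = set(estimators) - {
        "naive",
        "calibrated",
        "ensemble_independent",
        "ensemble_joint",
    }
    if unknown:
        raise ValidationError(f"unknown estimators {sorted(unknown)}")

    master = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for scenario in scenarios:
        for M_name in M_names:
            companion = "M2" if M_name == "M3" else "M3"
            for n in n_values:
                cell_seed = master.spawn(1)[0]
                for rep in range(replicates):
                    rng = np.random.default_rng(cell_seed.spawn(1)[0])
                    spec = ScenarioSpec(
                        scenario=scenario, N=N, n=n, Ms=(M_name, companion)
                    )
                    ds = generate_dataset(spec, rng=rng)
                    base = {
                        "scenario": scenario,
                        "M": M_name,
                        "n": n,
                        "replicate": rep,
                    }
                    vs = [ds.prediction_counts(k) for k in range(2)]
                    Ts = [ds.transfer_counts(k) for k in range(2)]

                    def emit(estimator, classifier, fn):
                        row = dict(base, estimator=estimator, classifier=classifier)
                        try:
                            row["csmfa"] = csmfa(fn(), ds.p_U)
                            row["error"] = ""
                        except Exception as exc:  # recorded, not fatal
                            row["csmfa"] = np.nan
                            row["error"] = f"{type(exc).__name__}: {exc}"
                        rows.append(row)

                    for k in range(2):
                        if "naive" in estimators:
                            emit("naive", k + 1, lambda k=k: vs[k].naive_q)
                        if "calibrated" in estimators:
                            emit(
                                "calibrated",
                                k + 1,
                                lambda k=k: gibbs_single(
                                    vs[k], Ts[k], hyper, control
                                ).p_mean,
                            )
                    if "ensemble_independent" in estimators:
                        emit(
                            "ensemble_independent",
                            0,
                            lambda: ens.gibbs_independent(vs, Ts, hyper, control).p_mean,
                        )
                    if "ensemble_joint" in estimators:
                        names = np.asarray(ds.space.classes)
                        emit(
                            "ensemble_joint",
                            0,
                            lambda: ens.gibbs_joint(
                                ens.tabulate_combinations(
                                    names[ds.unlabeled_pred], ds.space
                                ),
                                Ts,
                                hyper,
                                control,
                            ).p_mean,
                        )
    return pd.DataFrame(rows)
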