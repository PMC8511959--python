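"""CSMF accuracy and posterior summarization."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .model_core import PosteriorDraws, ValidationError, check_csmf

__all__ = ["csmfa", "summarize"]


def csmfa(p_est: np.ndarray, p_true: np.ndarray) -> float:
    """CSMF accuracy of an estimate against the true class-probability vector.

    ``1 - ||p_est - p_true||_1 / (2 (1 - min p_true))``: equals 1 iff the two
    vectors coincide, and 0 for the worst possible estimate (a point mass on
    the rarest true class).  Note the metric is not symmetric — the
    denominator is the worst-case L1 distance from ``p_true``.
    """
    p_est = check_csmf(p_est)
    p_true = check_csmf(p_true)
    if p_est.shape != p_true.shape:
        raise ValidationError("CSMF vectors must have equal length")
    denom = 2.0 * (1.0 - p_true.min())
    if denom <= 0:
        raise ValidationError("degenerate reference CSMF (min p_true = 1)")
    return float(1.0 - np.abs(p_est - p_true).sum() / denom)


def _flat_names(name: str, shape: tuple[int, ...]):
    if shape == ():
        yield name
        return
    for idx in np.ndindex(shape):
        yield f"{name}[{','.join(map(str, idx))}]"


def summarize(
    draws: "PosteriorDraws | Mapping[str, np.ndarray]",
    probs: tuple[float, ...] = (0.025, 0.5, 0.975),
) -> pd.DataFrame:
    """Posterior summary table: mean, sd, quantiles, split-Rhat and ESS.

    Accepts a :class:`PosteriorDraws` or a mapping of parameter name to a
    chain-major array of shape (chains, draws, ...).  Quantiles use the
    linear (type-7) interpolation rule.  Rhat/ESS (via ArviZ) are reported
    when at least two chains are present.
    """
    import arviz as az

    params = draws.to_param_dict() if isinstance(draws, PosteriorDraws) else dict(draws)
    if not params:
        raise ValidationError("no parameters to summarize")

    rows = []
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim < 2 or arr.shape[1] == 0:
            raise ValidationError(f"parameter {name!r} has no draws")
        n_chains = arr.shape[0]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        if n_chains >= 2:
            ds = az.convert_to_dataset(arr)
            rhat = np.asarray(az.rhat(ds)["x"]).reshape(-1)
            ess = np.asarray(az.ess(ds)["x"]).reshape(-1)
        else:
            rhat = np.full(flat.shape[2], np.nan)
            ess = np.asarray(az.ess(az.convert_to_dataset(arr))["x"]).reshape(-1)
        qs = np.quantile(flat, probs, axis=(0, 1))
        means = flat.mean(axis=(0, 1))
        sds = flat.std(axis=(0, 1), ddof=1)
        for col, pname in enumerate(_flat_names(name, arr.shape[2:])):
            row = {
                "parameter": pname,
                "mean": means[col],
                "sd": sds[col],
                **{f"q{100 * q:g}": qs[j, col] for j, q in enumerate(probs)},
                "rhat": rhat[col],
                "ess": ess[col],
            }
            rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
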