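"""Delimited-text readers/writers, run configuration, and orchestration.

Input schema (comma-delimited by default):

* unlabeled set — columns ``id`` and ``predicted`` (single classifier) or
  ``predicted_<name>`` (one per classifier);
* labeled set — the same prediction columns plus ``true``;
* optional covariate columns joined on ``id``.

Outputs per run: a long-format draw table (chain, iteration, parameter,
index, value), a summary table, and a JSON metadata sidecar (seed,
hyperparameters, acceptance rates) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import ensemble as ens
from .metrics import summarize
from .model_core import (
    Hyperparams,
    LabelSpace,
    PosteriorDraws,
    SamplerControl,
    ValidationError,
    gibbs_single,
    tabulate_predictions,
    tabulate_transfer,
)

__all__ = [
    "RunConfig",
    "load_config",
    "read_unlabeled",
    "read_labeled",
    "write_draws",
    "write_summary",
    "run",
]

logger = logging.getLogger("vacalib")

_VARIANTS = ("single", "ensemble-independent", "ensemble-joint", "covariate")


@dataclass
class RunConfig:
    variant: str = "single"
    unlabeled: str = ""
    labeled: str = ""
    classes: tuple[str, ...] | None = None
    classifiers: tuple[str, ...] | None = None  # suffixes of predicted_<name> columns
    covariate_spec: tuple[tuple[str, str], ...] = ()
    delimiter: str = ","
    hyper: Hyperparams = field(default_factory=Hyperparams)
    control: SamplerControl = field(default_factory=SamplerControl)
    outdir: str = "vacalib_out"

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}; choose {_VARIANTS}")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML config; keyword overrides (e.g. from CLI flags) win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a mapping")
    hyper = Hyperparams(**raw.pop("hyperparams", {}))
    control = SamplerControl(**raw.pop("sampler", {}))
    cov_spec = tuple(
        (c["name"], c.get("kind", "categorical")) for c in raw.pop("covariates", [])
    )
    classes = raw.pop("classes", None)
    kwargs = dict(
        raw,
        hyper=hyper,
        control=control,
        covariate_spec=cov_spec,
        classes=tuple(classes) if classes else None,
    )
    kwargs.update(overrides)
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ValidationError(f"bad config key: {exc}") from exc


def _prediction_columns(df: pd.DataFrame, classifiers=None) -> list[str]:
    if classifiers:
        cols = [f"predicted_{name}" for name in classifiers]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"missing prediction column(s) {missing}")
        return cols
    if "predicted" in df.columns:
        return ["predicted"]
    cols = [c for c in df.columns if c.startswith("predicted_")]
    if not cols:
        raise ValidationError(
            "no 'predicted' or 'predicted_<name>' column found in input"
        )
    return cols


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'id'")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate id {dup!r}")
    return df


def read_unlabeled(
    path: str | Path, delimiter: str = ",", classifiers=None
) -> tuple[pd.DataFrame, list[str]]:
    """Read the unlabeled prediction table; returns (frame, prediction columns)."""
    df = _read_table(path, delimiter)
    return df, _prediction_columns(df, classifiers)


def read_labeled(
    path: str | Path, delimiter: str = ",", classifiers=None
) -> tuple[pd.DataFrame, list[str]]:
    """Read the labeled (true, predicted) table; returns (frame, prediction columns)."""
    df = _read_table(path, delimiter)
    if "true" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'true'")
    return df, _prediction_columns(df, classifiers)


def infer_space(config: RunConfig, *frames_and_cols) -> LabelSpace:
    """Label space from config, or the sorted union over all label columns."""
    if config.classes:
        return LabelSpace(config.classes)
    seen: set[str] = set()
    for df, cols in frames_and_cols:
        for c in cols:
            seen.update(df[c].dropna().astype(str))
    space = LabelSpace(tuple(sorted(seen)))
    logger.info("label space inferred as sorted union: %s", space.classes)
    return space


def write_draws(draws: PosteriorDraws, path: str | Path, delimiter: str = ","):
    """Write draws in long format: chain, iteration, parameter, index, value."""
    records = []
    for name, arr in draws.to_param_dict().items():
        ch, dr = arr.shape[:2]
        flat = arr.reshape(ch, dr, -1)
        idx_names = [
            ",".join(map(str, idx)) for idx in np.ndindex(arr.shape[2:])
        ] or [""]
        for c in range(ch):
            for t in range(dr):
                for col, iname in enumerate(idx_names):
                    records.append((c, t, name, iname, flat[c, t, col]))
    pd.DataFrame(
        records, columns=["chain", "iteration", "parameter", "index", "value"]
    ).to_csv(path, sep=delimiter, index=False)


def write_summary(draws, path: str | Path, delimiter: str = ","):
    summarize(draws).to_csv(path, sep=delimiter)


def _metadata(config: RunConfig, draws: PosteriorDraws, space: LabelSpace) -> dict:
    return {
        "variant": config.variant,
        "classes": list(space.classes),
        "seed": config.control.seed,
        "hyperparams": vars(config.hyper).copy(),
        "sampler": {
            k: v for k, v in vars(config.control).items() if not k.startswith("_")
        },
        "acceptance_rates": np.asarray(draws.accept).tolist(),
    }


def run(config: RunConfig) -> dict:
    """Execute a full calibration run and write the artifact bundle.

    Returns a dict with the posterior object and the paths written.
    Deterministic given the master seed in ``config.control``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unl, unl_cols = read_unlabeled(config.unlabeled, config.delimiter, config.classifiers)
    lab, lab_cols = read_labeled(config.labeled, config.delimiter, config.classifiers)
    if len(unl_cols) != len(lab_cols):
        raise ValidationError(
            "labeled and unlabeled sets list different numbers of classifiers"
        )
    space = infer_space(config, (unl, unl_cols), (lab, [*lab_cols, "true"]))
    K = len(unl_cols)

    Ts = [
        tabulate_transfer(lab["true"].tolist(), lab[c].tolist(), space)
        for c in lab_cols
    ]
    for T in Ts:
        if (T.n_i == 0).any():
            zero = [space.classes[i] for i in np.flatnonzero(T.n_i == 0)]
            logger.warning("no labeled records for class(es) %s", zero)
    if config.hyper.delta == 0 and Ts[0].n == 0:
        logger.warning(
            "delta = 0 with an empty labeled set: theorem-limit behavior, "
            "the posterior mean of p will track v/N"
        )

    if config.variant == "covariate":
        design = cov.build_design(
            unl.rename(columns={unl_cols[0]: "predicted"}),
            list(config.covariate_spec),
            space,
        )
        draws = cov.gibbs_covariate(
            design, Ts[0], hyper=config.hyper, control=config.control
        )
        param_dict = {
            "beta": draws.beta,
            "M": draws.M,
            "gamma": draws.gamma,
            "p": draws.marginal_csmf_draws(),
        }
        summary_src: object = param_dict
        meta_space = space
    else:
        vs = [tabulate_predictions(unl[c].tolist(), space) for c in unl_cols]
        if config.variant == "single":
            if K != 1:
                raise ValidationError(
                    f"variant 'single' expects one classifier, found {K}"
                )
            draws = gibbs_single(vs[0], Ts[0], config.hyper, config.control)
        elif config.variant == "ensemble-independent":
            draws = ens.gibbs_independent(vs, Ts, config.hyper, config.control)
        else:  # ensemble-joint
            if K < 2:
                raise ValidationError(
                    "variant 'ensemble-joint' requires >= 2 classifiers; "
                    "use variant 'single' for one classifier"
                )
            y = ens.tabulate_combinations(unl[unl_cols].to_numpy(), space)
            draws = ens.gibbs_joint(y, Ts, config.hyper, config.control)
        param_dict = draws.to_param_dict()
        summary_src = draws
        meta_space = space

    draws_path = outdir / "draws.csv"
    summary_path = outdir / "summary.csv"
    meta_path = outdir / "metadata.json"
    if config.variant == "covariate":
        # long-format writer works off the parameter dict directly
        records = []
        for name, arr in param_dict.items():
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            idx_names = [
                ",".join(map(str, idx)) for idx in np.ndindex(arr.shape[2:])
            ] or [""]
            for c in range(arr.shape[0]):
                for t in range(arr.shape[1]):
                    for col, iname in enumerate(idx_names):
                        records.append((c, t, name, iname, flat[c, t, col]))
        pd.DataFrame(
            records, columns=["chain", "iteration", "parameter", "index", "value"]
        ).to_csv(draws_path, sep=config.delimiter, index=False)
        summarize(param_dict).to_csv(summary_path, sep=config.delimiter)
        meta = {
            "variant": config.variant,
            "classes": list(meta_space.classes),
            "seed": config.control.seed,
            "hyperparams": vars(config.hyper).copy(),
            "sampler": vars(config.control).copy(),
            "acceptance_rates": np.asarray(draws.accept).tolist(),
        }
    else:
        write_draws(draws, draws_path, config.delimiter)
        write_summary(summary_src, summary_path, config.delimiter)
        meta = _metadata(config, draws, meta_space)
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    logger.info("run complete: %s", outdir)
    return {
        "draws": draws,
        "paths": {
            "draws": str(draws_path),
            "summary": str(summary_path),
            "metadata": str(meta_path),
        },
    }
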