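"""Survey readers/writers, run configuration and the pipeline driver.

Survey tables travel as delimited text with a one-line header of node
names; an empty cell is a missing value, never a distinct state.  Networks
travel as the JSON layout documented on :class:`sibbn.bn_core.NetworkSpec`.
A full run (simulate → fit → validate → sweep → scenario) is reproducible
from its configuration alone: every seed is explicit and recorded in the
run log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bn_core import NetworkSpec
from .evaluation import cross_validate
from .learning import SurveyTable, em_fit
from .sensitivity import best_states, predictive_inference, run_scenario
from .si_model import ECOLI_POU, ModelVariant, build_model
from .synthetic_data import GeneratorConfig, generate

__all__ = ["RunConfig", "read_survey", "write_survey", "run_pipeline"]


class SurveyFormatError(ValueError):
    """Malformed survey file: bad header, delimiter or state label."""


def read_survey(path, schema: NetworkSpec, sep: str = ",") -> SurveyTable:
    """Read a delimited survey file against a network schema.

    Header names must be node names of ``schema`` (extra columns are
    rejected; absent columns are simply absent fields).  Empty cells become
    missing values.  An unknown state label is rejected with its row and
    column coordinates.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in schema.nodes]
    if unknown:
        raise SurveyFormatError(
            f"{path}: header names unknown nodes {unknown}"
        )
    if df.empty:
        raise SurveyFormatError(f"{path}: no records")
    records: list[dict[str, str | None]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec: dict[str, str | None] = {}
        for col, val in zip(df.columns, row):
            if val == "":
                rec[col] = None
            elif val in schema.states(col):
                rec[col] = val
            else:
                raise SurveyFormatError(
                    f"{path}: row {i + 2}, column {col!r}: illegal state "
                    f"{val!r} (legal: {list(schema.states(col))})"
                )
        records.append(rec)
    return SurveyTable(records)


def write_survey(table: SurveyTable, path, sep: str = ",") -> None:
    df = table.to_dataframe()
    df.to_csv(path, sep=sep, index=False, na_rep="")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to a single file."""

    variant: str = "1B"
    n: int = 328
    poc_missing: int = 49
    seed: int = 0
    # EM settings
    prior_count: float = 1.0
    tol: float = 1e-6
    max_iter: int = 200
    # cross-validation settings
    k: int = 10
    stages: tuple[str, ...] = ("simulate", "fit", "validate", "sweep", "scenario")
    out_dir: str = "sibbn_run"
    survey_path: str | None = None  # use an existing table instead of simulating

    def __post_init__(self) -> None:
        ModelVariant.parse(self.variant)
        if self.n < 1 or not 0 <= self.poc_missing <= self.n:
            raise ValueError("need n >= 1 and 0 <= poc_missing <= n")
        if self.prior_count < 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid EM settings")
        if not 2 <= self.k <= self.n:
            raise ValueError("invalid fold count")
        bad = set(self.stages) - {"simulate", "fit", "validate", "sweep",
                                  "scenario"}
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        if "simulate" not in self.stages and self.survey_path is None:
            raise ValueError("need either the simulate stage or survey_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages in order; returns the artifact directory.

    Artifacts: config echo, run log (seeds, iteration counts), survey table,
    truth and fitted networks (JSON), validation scores, ΔP table, scenario
    result.  Deterministic: the same config yields byte-identical numeric
    outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    log: dict = {"seed": cfg.seed, "variant": cfg.variant, "stages": []}
    ss = np.random.SeedSequence(cfg.seed)
    s_sim, s_cv = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    variant = ModelVariant.parse(cfg.variant)
    structure = build_model(variant)

    if "simulate" in cfg.stages:
        bundle = generate(
            variant, config=GeneratorConfig(
                variant=variant.tag, n=cfg.n,
                poc_missing=cfg.poc_missing, seed=s_sim,
            ),
        )
        table = bundle.table
        bundle.truth.to_json(out / "truth_network.json")
        write_survey(table, out / "survey.csv")
        log["stages"].append({"stage": "simulate", "seed": s_sim,
                              "n": cfg.n, "poc_missing": cfg.poc_missing})
    else:
        table = read_survey(cfg.survey_path, structure)
        log["stages"].append({"stage": "load", "path": cfg.survey_path,
                              "n": len(table)})

    fit = None
    if "fit" in cfg.stages:
        fit = em_fit(structure, table, prior_count=cfg.prior_count,
                     tol=cfg.tol, max_iter=cfg.max_iter, init="uniform")
        fit.network.to_json(out / "fitted_network.json")
        (out / "loglik_trace.json").write_text(
            json.dumps(fit.loglik_trace))
        log["stages"].append({
            "stage": "fit", "iterations": fit.n_iter,
            "converged": fit.converged, "loglik": fit.loglik,
        })

    if "validate" in cfg.stages:
        report = cross_validate(
            variant, table, k=cfg.k, seed=s_cv,
            prior_count=cfg.prior_count, tol=cfg.tol, max_iter=cfg.max_iter,
        )
        pd.DataFrame({
            "score": report.scores, "label": report.labels,
            "fold": report.fold_of,
        }).to_csv(out / "cv_scores.csv", index=False)
        log["stages"].append({
            "stage": "validate", "seed": s_cv, "k": cfg.k,
            "auc": report.auc, "class": report.accuracy_class,
        })

    if fit is not None and "sweep" in cfg.stages:
        dp = predictive_inference(fit.network)
        dp.to_frame().to_csv(out / "delta_p.csv", index=False)
        log["stages"].append({"stage": "sweep",
                              "baseline_pct": dp.baseline})

    if fit is not None and "scenario" in cfg.stages:
        sc = best_states(variant)
        updated, baseline = run_scenario(fit.network, sc)
        result = {"scenario": sc.as_dict(), "outcome": ECOLI_POU,
                  "updated_pct": updated, "baseline_pct": baseline}
        (out / "scenario.json").write_text(json.dumps(result, indent=1))
        log["stages"].append({"stage": "scenario", "updated_pct": updated,
                              "baseline_pct": baseline})

    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return out
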