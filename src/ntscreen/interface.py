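"""Configuration loading, cohort file I/O and the end-to-end pipeline.

Cohort files are flat comma-delimited text with a header
(``id,crl_mm,nt_mm,maternal_age_years,status`` plus an optional
truth-tracking ``component`` column); the configuration is hierarchical
YAML.  ``run_pipeline`` chains simulation, MoM-parameter derivation,
scoring, evaluation, calibration and the sensitivity analysis, writing
delimited tables plus a JSON run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    DEFAULT_DR_TARGETS,
    DEFAULT_FPR_TARGETS,
    ScoreSet,
    median_risk_by_status,
    performance_table,
    quintile_calibration,
    roc_from_scores,
    sensitivity_analysis,
)
from .mixture_model import (
    CRL_MAX,
    CRL_MIN,
    DependentComponentParams,
    IndependentComponentParams,
    MixtureModelParams,
    ProportionCurve,
    Status,
    TruncationLimits,
    likelihood_ratio_mixture,
)
from .mom_method import (
    MedianCurve,
    WeekAnchors,
    derive_mom_params,
    mom_params_to_frame,
    nt_to_mom,
    score_mom,
    week_for_crl,
)
from .risk_engine import AgeRiskCurve, posterior_probability
from .synthetic_data import COHORT_COLUMNS, CohortSpec, simulate_cohort, truncate_cohort

__all__ = ["ConfigError", "RunConfig", "default_config_path", "load_config",
           "load_mixture_params", "read_cohort", "write_cohort", "write_tables",
           "score_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration key is missing or malformed."""


def default_config_path() -> Path:
    """Path of the packaged synthetic-defaults configuration."""
    return Path(resources.files("ntscreen") / "data" / "synthetic_defaults.yaml")


def _get(d: dict, dotted: str):
    node = d
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"missing configuration key: {dotted}")
        node = node[part]
    return node


def _number(d: dict, dotted: str) -> float:
    v = _get(d, dotted)
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"configuration key {dotted} must be a number, got {v!r}")
    return float(v)


def load_mixture_params(cfg: dict) -> MixtureModelParams:
    """Build MixtureModelParams from a parsed config, naming any bad key."""
    try:
        dep = DependentComponentParams(
            a=_number(cfg, "mixture.unaffected.dependent.a"),
            b=_number(cfg, "mixture.unaffected.dependent.b"),
            c=_number(cfg, "mixture.unaffected.dependent.c"),
            sigma=_number(cfg, "mixture.unaffected.dependent.sigma"),
        )
        ind_u = IndependentComponentParams(
            mu=_number(cfg, "mixture.unaffected.independent.mu"),
            sigma=_number(cfg, "mixture.unaffected.independent.sigma"),
        )
        prop = ProportionCurve(
            p_at_45=_number(cfg, "mixture.unaffected.proportion.p45"),
            p_at_84=_number(cfg, "mixture.unaffected.proportion.p84"),
            form=str(_get(cfg, "mixture.unaffected.proportion.form")),
        )
        ind_a = IndependentComponentParams(
            mu=_number(cfg, "mixture.affected.independent.mu"),
            sigma=_number(cfg, "mixture.affected.independent.sigma"),
        )
        trunc = TruncationLimits(
            lower=_number(cfg, "truncation.lower"),
            upper=_number(cfg, "truncation.upper"),
            scale=str(_get(cfg, "truncation.scale")),
        )
        return MixtureModelParams(
            unaffected_dep=dep,
            unaffected_ind=ind_u,
            unaffected_prop=prop,
            affected_ind=ind_a,
            affected_prop_ind=_number(cfg, "mixture.affected.prop_independent"),
            truncation=trunc,
        )
    except ValueError as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError(f"invalid mixture configuration: {e}") from e


def _load_week_anchors(cfg: dict) -> WeekAnchors:
    weeks = cfg.get("weeks")
    if weeks is None:
        return WeekAnchors()
    anchors = {int(k): float(v) for k, v in _get(cfg, "weeks.anchors").items()}
    boundaries = tuple(float(x) for x in _get(cfg, "weeks.boundaries"))
    return WeekAnchors(anchors=anchors, boundaries=boundaries)


def _load_age_risk(cfg: dict) -> AgeRiskCurve:
    kind = str(_get(cfg, "age_risk.kind"))
    if kind == "table":
        table = _get(cfg, "age_risk.table")
        ages = [row[0] for row in table]
        risks = [row[1] for row in table]
        return AgeRiskCurve.from_table(ages, risks)
    if kind == "parametric":
        return AgeRiskCurve.from_regression(
            base=_number(cfg, "age_risk.base"),
            intercept=_number(cfg, "age_risk.intercept"),
            slope=_number(cfg, "age_risk.slope"),
        )
    if kind == "constant":
        return AgeRiskCurve.constant(_number(cfg, "age_risk.p"))
    raise ConfigError(f"age_risk.kind must be table/parametric/constant, got {kind!r}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    params: MixtureModelParams
    anchors: WeekAnchors
    age_risk: AgeRiskCurve
    n_affected: int = 104
    n_unaffected: int = 22284
    fpr_targets: Sequence[float] = DEFAULT_FPR_TARGETS
    dr_targets: Sequence[float] = DEFAULT_DR_TARGETS
    method: str = "both"
    seed: int = 0
    cohort_path: Optional[Path] = None
    out_dir: Path = field(default_factory=lambda: Path("ntscreen_out"))

    def __post_init__(self):
        if self.method not in ("mixture", "mom", "both"):
            raise ConfigError(f"method must be mixture/mom/both, got {self.method!r}")
        for t in list(self.fpr_targets) + list(self.dr_targets):
            if not (0.0 < t < 1.0):
                raise ConfigError(f"FPR/DR target {t} outside (0, 1)")


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML configuration file (the packaged defaults when ``path`` is
    None) into a validated RunConfig; keyword overrides win."""
    path = Path(path) if path is not None else default_config_path()
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = dict(
        params=load_mixture_params(cfg),
        anchors=_load_week_anchors(cfg),
        age_risk=_load_age_risk(cfg),
        n_affected=int(_number(cfg, "cohort.n_affected")),
        n_unaffected=int(_number(cfg, "cohort.n_unaffected")),
        fpr_targets=tuple(_get(cfg, "evaluation.fpr_targets")),
        dr_targets=tuple(_get(cfg, "evaluation.dr_targets")),
    )
    base.update(overrides)
    return RunConfig(**base)


def read_cohort(path, on_out_of_range: str = "error") -> pd.DataFrame:
    """Read a cohort CSV, validating the schema row by row.

    ``on_out_of_range``: 'error' rejects CRL outside [45, 84] with the line
    number; 'truncate' routes sub-45 records to :func:`truncate_cohort`.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"cohort file {path} is missing columns: {missing}")
    bad_status = ~df["status"].isin([s.value for s in Status])
    if bad_status.any():
        line = int(df.index[bad_status][0]) + 2  # header is line 1
        raise ConfigError(f"{path}:{line}: invalid status {df.loc[bad_status, 'status'].iloc[0]!r}")
    bad_nt = ~(df["nt_mm"] > 0)
    if bad_nt.any():
        line = int(df.index[bad_nt][0]) + 2
        raise ConfigError(f"{path}:{line}: NT must be positive")
    out_of_range = (df["crl_mm"] < CRL_MIN) | (df["crl_mm"] > CRL_MAX)
    if out_of_range.any():
        if on_out_of_range == "truncate":
            high = df["crl_mm"] > CRL_MAX
            if high.any():
                line = int(df.index[high][0]) + 2
                raise ConfigError(f"{path}:{line}: CRL above {CRL_MAX:g} mm")
            df = truncate_cohort(df)
        else:
            line = int(df.index[out_of_range][0]) + 2
            raise ConfigError(
                f"{path}:{line}: CRL outside [{CRL_MIN:g}, {CRL_MAX:g}] mm "
                f"(value {df.loc[out_of_range, 'crl_mm'].iloc[0]:g})"
            )
    return df


def write_cohort(cohort: pd.DataFrame, path, with_truth: bool = False) -> None:
    cols = COHORT_COLUMNS + (["component"] if with_truth and "component" in cohort else [])
    cohort[cols].to_csv(path, index=False)


def score_cohort(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Score every pregnancy under both methods.

    Adds columns: mom (truncation-clamped MoM value), week, lr_mixture,
    lr_mom, prior, risk_mixture, risk_mom.
    """
    params = config.params
    curve = MedianCurve.from_params(params)
    mom_params = derive_mom_params(params, config.anchors)
    nt = cohort["nt_mm"].to_numpy(float)
    crl = cohort["crl_mm"].to_numpy(float)
    age = cohort["maternal_age_years"].to_numpy(float)

    out = cohort.copy()
    nt_clamped = params.truncation.clamp(nt) if params.truncation.scale == "mm" else nt
    mom = nt_to_mom(nt_clamped, crl, curve)
    if params.truncation.scale == "mom":
        mom = params.truncation.clamp(mom)
    out["mom"] = mom
    out["week"] = week_for_crl(crl, config.anchors)
    out["lr_mixture"] = likelihood_ratio_mixture(nt, crl, params, median_curve=curve)
    out["lr_mom"] = score_mom(nt, crl, curve, config.anchors, mom_params,
                              truncation=params.truncation)
    prior = config.age_risk(age)
    out["prior"] = prior
    out["risk_mixture"] = posterior_probability(prior, out["lr_mixture"].to_numpy())
    out["risk_mom"] = posterior_probability(prior, out["lr_mom"].to_numpy())
    return out


def _score_sets(scored: pd.DataFrame, column: str) -> ScoreSet:
    aff = scored.loc[scored["status"] == Status.AFFECTED.value, column].to_numpy()
    unaff = scored.loc[scored["status"] == Status.UNAFFECTED.value, column].to_numpy()
    return ScoreSet(affected=aff, unaffected=unaff)


def write_tables(tables: Dict[str, pd.DataFrame], out_dir) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Simulate (or load) a cohort, score both methods, and emit the
    performance, calibration and sensitivity tables plus a run log."""
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path, on_out_of_range="truncate")
        n_before = None
    else:
        spec = CohortSpec(params=config.params, n_affected=config.n_affected,
                          n_unaffected=config.n_unaffected, seed=config.seed)
        cohort = simulate_cohort(spec, with_truth=False)
        n_before = len(cohort)
    cohort = truncate_cohort(cohort)
    scored = score_cohort(cohort, config)

    methods = {"mixture": "lr_mixture", "mom": "lr_mom"}
    if config.method != "both":
        methods = {config.method: methods[config.method]}

    tables: Dict[str, pd.DataFrame] = {}
    for name, lr_col in methods.items():
        roc = roc_from_scores(_score_sets(scored, lr_col))
        tables[f"performance_{name}"] = performance_table(
            roc, config.fpr_targets, config.dr_targets)
        risks = _score_sets(scored, f"risk_{name}")
        tables[f"calibration_{name}"] = quintile_calibration(risks).to_frame()
        med_aff, med_unaff = median_risk_by_status(risks)
        tables[f"median_risk_{name}"] = pd.DataFrame(
            [{"affected": med_aff, "unaffected": med_unaff}])

    mom_params = derive_mom_params(config.params, config.anchors)
    tables["derived_mom_params"] = mom_params_to_frame(mom_params)
    if "mom" in methods:
        by_status = {
            s: scored.loc[scored["status"] == s, "mom"].to_numpy() for s in
            ("affected", "unaffected")
        }
        weeks = {
            s: scored.loc[scored["status"] == s, "week"].to_numpy() for s in
            ("affected", "unaffected")
        }
        sens = sensitivity_analysis(by_status, weeks, mom_params,
                                    fpr_targets=config.fpr_targets,
                                    dr_targets=config.dr_targets)
        rows = []
        for sc, table in sens:
            row = {"target": sc.target, "factor": sc.factor}
            row.update(table.iloc[0].to_dict())
            rows.append(row)
        tables["sensitivity_mom"] = pd.DataFrame(rows)

    paths = write_tables(tables, config.out_dir)
    run_log = {
        "ntscreen_version": __version__,
        "seed": config.seed,
        "method": config.method,
        "n_records_input": n_before if n_before is not None else int(len(cohort)),
        "n_records_scored": int(len(cohort)),
        "n_excluded_crl_below_45": (n_before - len(cohort)) if n_before is not None else 0,
        "numpy_version": np.__version__,
        "tables": {k: str(v) for k, v in paths.items()},
    }
    with open(Path(config.out_dir) / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    return {"cohort": scored, "tables": tables, "run_log": run_log}
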