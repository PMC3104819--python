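"""Screening-performance and risk-calibration summaries.

Covers the empirical ROC trade-off (detection rate at fixed false-positive
rate and vice versa), the quintile-based risk-calibration table (categories
defined by quintiles of risk among affected pregnancies), median risk by
status, and the +/-20% sensitivity analysis on the derived MoM parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .mom_method import MoMParams, likelihood_ratio_mom
from .risk_engine import format_one_in_n

__all__ = [
    "ScoreSet",
    "ROCTable",
    "CalibrationRow",
    "CalibrationTable",
    "SensitivityScenario",
    "roc_from_scores",
    "dr_at_fpr",
    "fpr_at_dr",
    "performance_table",
    "quintile_calibration",
    "median_risk_by_status",
    "sensitivity_analysis",
    "default_scenarios",
    "DEFAULT_FPR_TARGETS",
    "DEFAULT_DR_TARGETS",
]

DEFAULT_FPR_TARGETS = (0.01, 0.03, 0.05, 0.10)
DEFAULT_DR_TARGETS = (0.50, 0.60, 0.70, 0.80, 0.90)


class CalibrationError(ValueError):
    """Quintile categories are degenerate (excessive ties in the risks)."""


@dataclass(frozen=True)
class ScoreSet:
    """Per-pregnancy scores (LRs or posterior risks) for one method."""

    affected: np.ndarray
    unaffected: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "affected", np.asarray(self.affected, dtype=float))
        object.__setattr__(self, "unaffected", np.asarray(self.unaffected, dtype=float))
        if self.affected.size == 0 or self.unaffected.size == 0:
            raise ValueError("both score groups must be nonempty")
        if not (np.all(np.isfinite(self.affected)) and np.all(np.isfinite(self.unaffected))):
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class ROCTable:
    """Empirical ROC: thresholds (descending) with DR and FPR at 'score >= t'.

    Starts at the (0, 0) operating point (threshold above every score) and
    ends at (1, 1); tied scores share a single threshold row.
    """

    thresholds: np.ndarray
    dr: np.ndarray
    fpr: np.ndarray


def roc_from_scores(scores: ScoreSet) -> ROCTable:
    """Threshold sweep over the pooled unique scores, highest first."""
    thresholds = np.unique(np.concatenate([scores.affected, scores.unaffected]))[::-1]
    aff_sorted = np.sort(scores.affected)
    unaff_sorted = np.sort(scores.unaffected)
    n_aff, n_unaff = aff_sorted.size, unaff_sorted.size
    # count of scores >= t via searchsorted on the ascending sort
    dr = (n_aff - np.searchsorted(aff_sorted, thresholds, side="left")) / n_aff
    fpr = (n_unaff - np.searchsorted(unaff_sorted, thresholds, side="left")) / n_unaff
    thresholds = np.concatenate([[np.inf], thresholds])
    dr = np.concatenate([[0.0], dr])
    fpr = np.concatenate([[0.0], fpr])
    return ROCTable(thresholds=thresholds, dr=dr, fpr=fpr)


def dr_at_fpr(roc: ROCTable, fpr: float, interpolate: bool = False) -> float:
    """Largest detection rate achievable with FPR <= target.

    The default readout is the conservative step function; ``interpolate``
    draws a straight line between the adjacent empirical operating points.
    """
    if not (0.0 < fpr <= 1.0):
        raise ValueError("target FPR must lie in (0, 1]")
    ok = roc.fpr <= fpr
    base = float(np.max(roc.dr[ok])) if ok.any() else 0.0
    if not interpolate:
        return base
    above = roc.fpr > fpr
    if not above.any():
        return base
    i = int(np.argmax(above))  # first point beyond the target
    x0, y0, x1, y1 = roc.fpr[i - 1], roc.dr[i - 1], roc.fpr[i], roc.dr[i]
    if x1 == x0:
        return base
    return float(y0 + (y1 - y0) * (fpr - x0) / (x1 - x0))


def fpr_at_dr(roc: ROCTable, dr: float, interpolate: bool = False) -> float:
    """Smallest false-positive rate achieving DR >= target."""
    if not (0.0 < dr <= 1.0):
        raise ValueError("target DR must lie in (0, 1]")
    ok = roc.dr >= dr
    base = float(np.min(roc.fpr[ok])) if ok.any() else 1.0
    if not interpolate:
        return base
    below = roc.dr < dr
    if not below.any() or not ok.any():
        return base
    i = int(np.argmax(ok))  # first point reaching the target DR
    if i == 0:
        return base
    x0, y0, x1, y1 = roc.dr[i - 1], roc.fpr[i - 1], roc.dr[i], roc.fpr[i]
    if x1 == x0:
        return base
    return float(y0 + (y1 - y0) * (dr - x0) / (x1 - x0))


def performance_table(roc: ROCTable,
                      fpr_targets: Sequence[float] = DEFAULT_FPR_TARGETS,
                      dr_targets: Sequence[float] = DEFAULT_DR_TARGETS,
                      interpolate: bool = False) -> pd.DataFrame:
    """One-row table of DR(%) at fixed FPRs and FPR(%) at fixed DRs."""
    row = {}
    for f in fpr_targets:
        row[f"dr_pct_at_fpr_{100 * f:g}"] = 100.0 * dr_at_fpr(roc, f, interpolate)
    for d in dr_targets:
        row[f"fpr_pct_at_dr_{100 * d:g}"] = 100.0 * fpr_at_dr(roc, d, interpolate)
    return pd.DataFrame([row])


@dataclass(frozen=True)
class CalibrationRow:
    category_bound: str
    n_affected: int
    n_total: int
    median_expected_risk: str
    observed_prevalence: str
    median_expected_risk_p: float
    observed_prevalence_p: float


@dataclass(frozen=True)
class CalibrationTable:
    rows: List[CalibrationRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _category_sizes(n: int, k: int) -> np.ndarray:
    """Split n into k near-equal category sizes, remainder to the top (highest
    risk) categories."""
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return sizes


def quintile_calibration(risks: ScoreSet, n_categories: int = 5) -> CalibrationTable:
    """Risk-calibration table over categories defined by quintiles of risk in
    affected pregnancies.

    Category boundaries sit at the affected risk quintiles so the affected
    pregnancies split as evenly as possible (remainder to the higher-risk
    categories; boundary ties go to the higher-risk category).  Every
    pregnancy is then assigned by its own risk, and each category reports the
    affected count, the median estimated risk over all its pregnancies, and
    the observed prevalence affected/(affected+unaffected).
    """
    aff = risks.affected
    unaff = risks.unaffected
    if np.any((aff <= 0) | (aff >= 1)) or np.any((unaff <= 0) | (unaff >= 1)):
        raise ValueError("calibration expects posterior risks in (0, 1)")
    if aff.size < n_categories:
        raise ValueError(f"need at least {n_categories} affected pregnancies")

    aff_desc = np.sort(aff)[::-1]
    sizes = _category_sizes(aff.size, n_categories)
    cut_idx = np.cumsum(sizes)[:-1] - 1
    bounds = aff_desc[cut_idx]  # lower bound (inclusive) of each upper category
    if np.unique(bounds).size < bounds.size:
        tie_mass = int(np.max(np.unique(aff, return_counts=True)[1]))
        raise CalibrationError(
            f"quintile boundaries are degenerate: a tie of {tie_mass} identical "
            "risks spans more than one category"
        )

    def assign(values):
        # category 0 = highest risk; values equal to a bound go to the
        # higher-risk side
        return np.searchsorted(-bounds, -np.asarray(values), side="left")

    cat_aff = assign(aff)
    cat_unaff = assign(unaff)
    rows = []
    for k in range(n_categories):
        in_aff = aff[cat_aff == k]
        in_unaff = unaff[cat_unaff == k]
        pooled = np.concatenate([in_aff, in_unaff])
        n_a, n_tot = in_aff.size, pooled.size
        prev = n_a / n_tot if n_tot else np.nan
        med = float(np.median(pooled)) if n_tot else np.nan
        if k == 0:
            bound_text = "≥" + format_one_in_n(bounds[0])
        elif k == n_categories - 1:
            bound_text = "≤" + format_one_in_n(bounds[-1])
        else:
            bound_text = format_one_in_n(bounds[k - 1])
        rows.append(
            CalibrationRow(
                category_bound=bound_text,
                n_affected=int(n_a),
                n_total=int(n_tot),
                median_expected_risk=format_one_in_n(med) if n_tot else "",
                observed_prevalence=format_one_in_n(prev) if 0 < prev < 1 else
                ("1 in 1.0" if prev == 1 else ""),
                median_expected_risk_p=med,
                observed_prevalence_p=prev,
            )
        )
    return CalibrationTable(rows)


def median_risk_by_status(risks: ScoreSet) -> Tuple[str, str]:
    """Median posterior risk per status as "1 in n" (lower-median for even
    counts, i.e. the smaller of the two central risks)."""

    def lower_median(x):
        x = np.sort(x)
        return float(x[(x.size - 1) // 2])

    return (format_one_in_n(lower_median(risks.affected)),
            format_one_in_n(lower_median(risks.unaffected)))


@dataclass(frozen=True)
class SensitivityScenario:
    """One +/-20% perturbation of the derived MoM parameters.

    ``target`` is one of 'affected_median_mom', 'affected_sd',
    'unaffected_sd'; ``factor`` multiplies the targeted quantity.
    """

    target: str
    factor: float

    _TARGETS = ("affected_median_mom", "affected_sd", "unaffected_sd")

    def __post_init__(self):
        if self.target not in self._TARGETS:
            raise ValueError(f"unknown sensitivity target {self.target!r}")
        if self.factor <= 0:
            raise ValueError("factor must be positive")

    def apply(self, mom_params: Dict[int, MoMParams]) -> Dict[int, MoMParams]:
        kw = {
            "affected_median_mom": {"median_mom_factor": self.factor},
            "affected_sd": {"sd_affected_factor": self.factor},
            "unaffected_sd": {"sd_unaffected_factor": self.factor},
        }[self.target]
        return {wk: mp.perturbed(**kw) for wk, mp in mom_params.items()}


def default_scenarios() -> List[SensitivityScenario]:
    return [SensitivityScenario(target, f)
            for target in SensitivityScenario._TARGETS for f in (0.8, 1.2)]


def sensitivity_analysis(mom_by_status: Dict[str, np.ndarray],
                         weeks_by_status: Dict[str, np.ndarray],
                         mom_params: Dict[int, MoMParams],
                         scenarios: Sequence[SensitivityScenario] | None = None,
                         fpr_targets: Sequence[float] = DEFAULT_FPR_TARGETS,
                         dr_targets: Sequence[float] = DEFAULT_DR_TARGETS,
                         ) -> List[Tuple[SensitivityScenario, pd.DataFrame]]:
    """Rescore the cohort's MoM values under perturbed MoM parameters and
    recompute the DR/FPR performance table for each scenario.

    ``mom_by_status`` / ``weeks_by_status`` map 'affected' / 'unaffected' to
    the cohort's (already truncation-clamped) MoM values and completed weeks.
    """
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    out = []
    for sc in scenarios:
        perturbed = sc.apply(mom_params)
        scores = ScoreSet(
            affected=likelihood_ratio_mom(mom_by_status["affected"],
                                          weeks_by_status["affected"], perturbed),
            unaffected=likelihood_ratio_mom(mom_by_status["unaffected"],
                                            weeks_by_status["unaffected"], perturbed),
        )
        table = performance_table(roc_from_scores(scores), fpr_targets, dr_targets)
        out.append((sc, table))
    return out
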