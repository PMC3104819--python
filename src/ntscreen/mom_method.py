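"""Standard multiple-of-the-median (MoM) method derived from the mixture model.

The MoM method expresses each NT as a multiple of the unaffected median NT at
the same CRL and models log10-MoM with a single Gaussian per status at each
completed gestational week (11, 12, 13).  Here the per-week Gaussian
parameters are *derived* from the mixture model, not asserted: at the CRL
anchor of each week (49, 62 and 76 mm) the mean and SD of log10(NT / median)
are computed as moments of the mixture density by numerical integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .mixture_model import (
    CRL_MAX,
    CRL_MIN,
    LN10,
    MixtureModelParams,
    OutOfRangeError,
    Status,
    TruncationLimits,
    _check_crl,
    _check_nt,
    _status_components,
    ind_pdf,
    mean_log_nt_dependent,
    nt_cdf,
    support_upper,
)

__all__ = [
    "WeekAnchors",
    "MoMParams",
    "MedianCurve",
    "median_nt",
    "nt_to_mom",
    "week_for_crl",
    "derive_mom_params",
    "likelihood_ratio_mom",
    "score_mom",
    "mom_params_to_frame",
]


@dataclass(frozen=True)
class WeekAnchors:
    """CRL anchors for completed weeks 11-13 and the CRL interval partition.

    ``boundaries`` gives cut points (b0, b1, b2, b3) such that
    [b0, b1) -> 11, [b1, b2) -> 12, [b2, b3] -> 13.
    """

    anchors: Dict[int, float] = field(
        default_factory=lambda: {11: 49.0, 12: 62.0, 13: 76.0}
    )
    boundaries: Tuple[float, float, float, float] = (45.0, 55.0, 69.0, 84.0)

    def __post_init__(self):
        b = self.boundaries
        if not (b[0] < b[1] < b[2] < b[3]):
            raise ValueError(f"week boundaries must be increasing, got {b}")
        intervals = {11: (b[0], b[1]), 12: (b[1], b[2]), 13: (b[2], b[3])}
        for week, (lo, hi) in intervals.items():
            a = self.anchors[week]
            if not (lo <= a <= hi):
                raise ValueError(f"anchor {a} for week {week} outside its interval [{lo}, {hi}]")


@dataclass(frozen=True)
class MoMParams:
    """Single-Gaussian log10-MoM parameters for one completed week."""

    week: int
    crl_anchor: float
    mean_log_mom_affected: float
    sd_log_mom_affected: float
    mean_log_mom_unaffected: float
    sd_log_mom_unaffected: float

    def __post_init__(self):
        if not (self.sd_log_mom_affected > 0 and self.sd_log_mom_unaffected > 0):
            raise ValueError("log-MoM SDs must be positive")

    def perturbed(self, *, median_mom_factor=1.0, sd_affected_factor=1.0,
                  sd_unaffected_factor=1.0) -> "MoMParams":
        """Return a copy with the affected median MoM and/or SDs rescaled.

        A multiplicative shift of the affected median MoM is an additive
        shift of the affected log10-MoM mean by log10(factor).
        """
        return replace(
            self,
            mean_log_mom_affected=self.mean_log_mom_affected + math.log10(median_mom_factor),
            sd_log_mom_affected=self.sd_log_mom_affected * sd_affected_factor,
            sd_log_mom_unaffected=self.sd_log_mom_unaffected * sd_unaffected_factor,
        )


def median_nt(crl, params: MixtureModelParams) -> float:
    """Median NT (mm) of the unaffected mixture at the given CRL.

    The unique root of ``nt_cdf(x, crl, unaffected) = 0.5``, found by
    bracketed root-finding.  Accepts a scalar or an array of CRLs.
    """
    crl = _check_crl(crl)
    if crl.ndim > 0:
        return np.array([median_nt(float(c), params) for c in crl])
    hi = support_upper(params, crl)

    def f(x):
        return float(nt_cdf(x, crl, Status.UNAFFECTED, params)) - 0.5

    lo = 1e-9
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError(f"median bracketing failed on ({lo:g}, {hi:g}) at CRL {crl:g}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


class MedianCurve:
    """Continuous unaffected median-NT curve over CRL in [45, 84] mm.

    Built from exact root-finding on a dense CRL grid with monotone cubic
    interpolation in between; interpolation error is negligible because the
    median is smooth in CRL.
    """

    def __init__(self, crl_grid: np.ndarray, median_grid: np.ndarray):
        from scipy.interpolate import PchipInterpolator

        self.crl_grid = np.asarray(crl_grid, dtype=float)
        self.median_grid = np.asarray(median_grid, dtype=float)
        self._interp = PchipInterpolator(self.crl_grid, self.median_grid)

    @classmethod
    def from_params(cls, params: MixtureModelParams, n_grid: int = 157) -> "MedianCurve":
        grid = np.linspace(CRL_MIN, CRL_MAX, n_grid)
        med = median_nt(grid, params)
        return cls(grid, med)

    def __call__(self, crl):
        crl = _check_crl(crl)
        return self._interp(crl)


def nt_to_mom(nt, crl, curve: MedianCurve):
    """Convert NT (mm) to a multiple of the unaffected median at the same CRL."""
    nt = _check_nt(nt)
    return nt / curve(crl)


def week_for_crl(crl, anchors: WeekAnchors):
    """Completed gestational week (11, 12 or 13) for a CRL in [45, 84] mm."""
    crl = _check_crl(crl)
    b = anchors.boundaries
    week = np.where(crl < b[1], 11, np.where(crl < b[2], 12, 13))
    return week if np.ndim(crl) else int(week)


def _log_mom_moments(status, crl_anchor: float, med: float,
                     params: MixtureModelParams) -> Tuple[float, float]:
    """Mean and SD of log10(NT / med) under the mixture density at one CRL.

    The CRL-dependent (lognormal) component has closed-form log10 moments;
    the zero-truncated Gaussian component is integrated by adaptive
    quadrature over its support.
    """
    pi, ind, dep = _status_components(status, params, crl_anchor)
    log_med = math.log10(med)

    # dependent component: log10 NT ~ N(m, sigma^2)
    m = float(mean_log_nt_dependent(crl_anchor, dep))
    dep_mean = m - log_med
    dep_second = dep.sigma**2 + dep_mean**2

    # independent component: quadrature of log10(x/med)^k against its pdf
    upper = ind.mu + 12.0 * ind.sigma

    def moment(k):
        def f(x):
            return (np.log10(x) - log_med) ** k * ind_pdf(x, ind)

        val, _ = integrate.quad(f, 0.0, upper, epsabs=1e-10, epsrel=1e-10, limit=200,
                                points=[ind.mu])
        return val

    if pi > 0.0:
        ind_mean = moment(1)
        ind_second = moment(2)
    else:
        ind_mean = ind_second = 0.0

    mean = pi * ind_mean + (1.0 - pi) * dep_mean
    second = pi * ind_second + (1.0 - pi) * dep_second
    var = second - mean * mean
    if var <= 0:
        raise ArithmeticError(
            f"nonpositive derived log-MoM variance ({var:g}) at CRL {crl_anchor:g}"
        )
    return mean, math.sqrt(var)


def derive_mom_params(params: MixtureModelParams,
                      anchors: WeekAnchors | None = None) -> Dict[int, MoMParams]:
    """Derive per-week single-Gaussian log10-MoM parameters from the mixture.

    For each week's CRL anchor, the unaffected median ``m`` is located by
    root-finding and the mean/SD of log10(NT/m) are computed for each status
    as moments of the mixture density by numerical integration.
    """
    anchors = anchors or WeekAnchors()
    out: Dict[int, MoMParams] = {}
    for week, crl_anchor in sorted(anchors.anchors.items()):
        med = median_nt(crl_anchor, params)
        mean_a, sd_a = _log_mom_moments(Status.AFFECTED, crl_anchor, med, params)
        mean_u, sd_u = _log_mom_moments(Status.UNAFFECTED, crl_anchor, med, params)
        out[week] = MoMParams(
            week=week,
            crl_anchor=crl_anchor,
            mean_log_mom_affected=mean_a,
            sd_log_mom_affected=sd_a,
            mean_log_mom_unaffected=mean_u,
            sd_log_mom_unaffected=sd_u,
        )
    return out


def likelihood_ratio_mom(mom, week, mom_params: Dict[int, MoMParams],
                         truncation: TruncationLimits | None = None):
    """Gaussian log10-MoM density ratio (affected / unaffected) for a week.

    ``mom`` is clamped to MoM-scale truncation limits first when given.
    Accepts scalars or arrays (``week`` broadcasting elementwise).
    """
    mom = np.asarray(mom, dtype=float)
    if np.any(mom <= 0):
        raise OutOfRangeError("MoM values must be positive")
    if truncation is not None:
        if truncation.scale != "mom":
            raise ValueError("likelihood_ratio_mom expects MoM-scale truncation limits")
        mom = truncation.clamp(mom)
    week_arr = np.asarray(week)
    log_mom = np.log10(mom)

    def lr_for(wk, lm):
        try:
            mp = mom_params[int(wk)]
        except KeyError:
            raise KeyError(f"no MoM parameters for week {wk}") from None
        num = stats.norm.pdf(lm, loc=mp.mean_log_mom_affected, scale=mp.sd_log_mom_affected)
        den = stats.norm.pdf(lm, loc=mp.mean_log_mom_unaffected, scale=mp.sd_log_mom_unaffected)
        return num / den

    if week_arr.ndim == 0 and log_mom.ndim == 0:
        return float(lr_for(week_arr, log_mom))
    week_b, lm_b = np.broadcast_arrays(week_arr, log_mom)
    out = np.empty(lm_b.shape, dtype=float)
    for wk in np.unique(week_b):
        mask = week_b == wk
        out[mask] = lr_for(wk, lm_b[mask])
    return out


def score_mom(nt, crl, curve: MedianCurve, anchors: WeekAnchors,
              mom_params: Dict[int, MoMParams],
              truncation: TruncationLimits | None = None):
    """Full MoM-method scoring path: NT -> MoM -> weekly Gaussian LR.

    mm-scale truncation limits clamp the NT before the MoM conversion;
    MoM-scale limits clamp the MoM value itself.
    """
    nt = _check_nt(nt)
    crl = _check_crl(crl)
    mom_trunc = None
    if truncation is not None:
        if truncation.scale == "mm":
            nt = truncation.clamp(nt)
        else:
            mom_trunc = truncation
    mom = nt_to_mom(nt, crl, curve)
    week = week_for_crl(crl, anchors)
    return likelihood_ratio_mom(mom, week, mom_params, truncation=mom_trunc)


def mom_params_to_frame(mom_params: Dict[int, MoMParams]) -> pd.DataFrame:
    """Derived-parameter table: one row per completed week."""
    rows = [
        {
            "week": mp.week,
            "crl_anchor_mm": mp.crl_anchor,
            "mean_log10mom_affected": mp.mean_log_mom_affected,
            "sd_log10mom_affected": mp.sd_log_mom_affected,
            "mean_log10mom_unaffected": mp.mean_log_mom_unaffected,
            "sd_log10mom_unaffected": mp.sd_log_mom_unaffected,
        }
        for _, mp in sorted(mom_params.items())
    ]
    return pd.DataFrame(rows)
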