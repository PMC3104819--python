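"""Two-component Gaussian mixture for nuchal translucency (NT) conditional on
crown-rump length (CRL).

At each CRL in [45, 84] mm, NT in a given status group (Down's syndrome /
unaffected) is modelled as a mixture of

* a **CRL-dependent** component: Gaussian in log10(NT) whose mean follows a
  quadratic in CRL and whose log10-scale SD is constant across CRL, and
* a **CRL-independent** component: Gaussian in NT millimetres (truncated at
  zero, since NT is a positive length), identical at every CRL.

The mixing weight of the CRL-independent component declines with CRL in
unaffected pregnancies (anchored at two endpoint proportions) and is a fixed
fraction (default 94%) in affected pregnancies.  The affected CRL-dependent
component is, by construction, the unaffected CRL-dependent component.

Likelihood ratios (affected density over unaffected density) are evaluated
after clamping the observation to configurable truncation limits, so the
ratio is held constant outside the well-supported range of NT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "CRL_MIN",
    "CRL_MAX",
    "Status",
    "DependentComponentParams",
    "IndependentComponentParams",
    "ProportionCurve",
    "TruncationLimits",
    "MixtureModelParams",
    "mean_log_nt_dependent",
    "proportion_independent",
    "nt_density",
    "nt_cdf",
    "nt_component_ppf",
    "likelihood_ratio_mixture",
    "support_upper",
]

CRL_MIN = 45.0
CRL_MAX = 84.0

LN10 = np.log(10.0)


class Status(str, Enum):
    """Pregnancy outcome label: Down's syndrome ('affected') or 'unaffected'."""

    AFFECTED = "affected"
    UNAFFECTED = "unaffected"


class OutOfRangeError(ValueError):
    """Raised when a CRL or NT value lies outside the supported domain."""


def _check_crl(crl) -> np.ndarray:
    crl = np.asarray(crl, dtype=float)
    if np.any((crl < CRL_MIN) | (crl > CRL_MAX)):
        bad = np.atleast_1d(crl)[(np.atleast_1d(crl) < CRL_MIN) | (np.atleast_1d(crl) > CRL_MAX)]
        raise OutOfRangeError(
            f"CRL must lie in [{CRL_MIN:g}, {CRL_MAX:g}] mm; got {bad[:5]}"
        )
    return crl


def _check_nt(nt) -> np.ndarray:
    nt = np.asarray(nt, dtype=float)
    if np.any(nt <= 0):
        raise OutOfRangeError("NT must be positive (mm)")
    return nt


@dataclass(frozen=True)
class DependentComponentParams:
    """CRL-dependent component: log10(NT) ~ N(a + b*crl + c*crl^2, sigma^2).

    ``sigma`` is in log10 units and is assumed independent of CRL.
    """

    a: float
    b: float
    c: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"dependent-component sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class IndependentComponentParams:
    """CRL-independent component: NT (mm) ~ N(mu, sigma^2) truncated at zero."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"independent-component sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class ProportionCurve:
    """Mixing fraction of the CRL-independent component as a function of CRL.

    Anchored at CRL 45 and 84 mm; ``form`` selects the interpolation rule
    between the anchors ('linear' in probability, or 'logistic' meaning
    linear on the log-odds scale).
    """

    p_at_45: float
    p_at_84: float
    form: str = "linear"

    def __post_init__(self):
        if not (0.0 <= self.p_at_84 <= self.p_at_45 <= 1.0):
            raise ValueError(
                "proportion anchors must satisfy 0 <= p_at_84 <= p_at_45 <= 1; "
                f"got p_at_45={self.p_at_45}, p_at_84={self.p_at_84}"
            )
        if self.form not in ("linear", "logistic"):
            raise ValueError(f"unknown proportion curve form {self.form!r}")


@dataclass(frozen=True)
class TruncationLimits:
    """Clamping bounds applied to the observation before likelihood ratios.

    ``scale`` says which scale the limits live on: 'mm' (raw NT) or 'mom'
    (multiples of the median).
    """

    lower: float
    upper: float
    scale: str = "mm"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"truncation lower ({self.lower}) must be < upper ({self.upper})")
        if self.scale not in ("mm", "mom"):
            raise ValueError(f"truncation scale must be 'mm' or 'mom', got {self.scale!r}")

    def clamp(self, x):
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class MixtureModelParams:
    """The full 10-parameter mixture model for both statuses.

    Five free distribution parameters per status: for unaffected pregnancies
    the log-quadratic mean curve plus its SD and the independent component's
    mean/SD; for affected pregnancies the independent component's mean/SD and
    the mixing proportion (the affected CRL-dependent component reuses
    ``unaffected_dep`` by construction).  The proportion anchors of the
    unaffected curve complete the parameterisation.
    """

    unaffected_dep: DependentComponentParams
    unaffected_ind: IndependentComponentParams
    unaffected_prop: ProportionCurve
    affected_ind: IndependentComponentParams
    affected_prop_ind: float = 0.94
    truncation: TruncationLimits = field(
        default_factory=lambda: TruncationLimits(lower=0.6, upper=6.0, scale="mm")
    )

    def __post_init__(self):
        if not (0.0 <= self.affected_prop_ind <= 1.0):
            raise ValueError(f"affected_prop_ind must be in [0,1], got {self.affected_prop_ind}")

    @property
    def affected_dep(self) -> DependentComponentParams:
        """Affected CRL-dependent component == unaffected CRL-dependent one."""
        return self.unaffected_dep

    def with_(self, **kwargs) -> "MixtureModelParams":
        return replace(self, **kwargs)


def mean_log_nt_dependent(crl, p: DependentComponentParams):
    """Mean of log10(NT) for the CRL-dependent component: a + b*crl + c*crl^2."""
    crl = _check_crl(crl)
    return p.a + p.b * crl + p.c * crl * crl


def proportion_independent(crl, curve: ProportionCurve):
    """Mixing fraction of the CRL-independent component at the given CRL."""
    crl = _check_crl(crl)
    t = (crl - CRL_MIN) / (CRL_MAX - CRL_MIN)
    if curve.form == "linear":
        p = curve.p_at_45 + t * (curve.p_at_84 - curve.p_at_45)
    else:  # logistic: linear interpolation on the log-odds scale
        lo45 = _logit(curve.p_at_45)
        lo84 = _logit(curve.p_at_84)
        p = _expit(lo45 + t * (lo84 - lo45))
    return np.clip(p, 0.0, 1.0)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# -- component densities ----------------------------------------------------

def _dep_logpdf(nt, crl, p: DependentComponentParams):
    # lognormal (base 10): density of NT when log10(NT) ~ N(m(crl), sigma^2)
    m = p.a + p.b * crl + p.c * crl * crl
    z = (np.log10(nt) - m) / p.sigma
    return -0.5 * z * z - np.log(p.sigma * LN10 * np.sqrt(2.0 * np.pi)) - np.log(nt)


def dep_pdf(nt, crl, p: DependentComponentParams):
    return np.exp(_dep_logpdf(nt, crl, p))


def dep_cdf(nt, crl, p: DependentComponentParams):
    m = p.a + p.b * crl + p.c * crl * crl
    return stats.norm.cdf((np.log10(nt) - m) / p.sigma)


def dep_ppf(u, crl, p: DependentComponentParams):
    m = p.a + p.b * crl + p.c * crl * crl
    return 10.0 ** (m + p.sigma * stats.norm.ppf(u))


def ind_pdf(nt, p: IndependentComponentParams):
    # Gaussian in mm truncated at zero and renormalised (NT is a length)
    z_mass = stats.norm.sf(-p.mu / p.sigma)
    return stats.norm.pdf((nt - p.mu) / p.sigma) / (p.sigma * z_mass)


def ind_cdf(nt, p: IndependentComponentParams):
    lo = stats.norm.cdf(-p.mu / p.sigma)
    z_mass = 1.0 - lo
    return (stats.norm.cdf((nt - p.mu) / p.sigma) - lo) / z_mass


def ind_ppf(u, p: IndependentComponentParams):
    lo = stats.norm.cdf(-p.mu / p.sigma)
    return p.mu + p.sigma * stats.norm.ppf(lo + u * (1.0 - lo))


def _status_components(status, params: MixtureModelParams, crl):
    """Return (pi_independent, ind_params, dep_params) for the status."""
    status = Status(status)
    if status is Status.AFFECTED:
        pi = params.affected_prop_ind
        return pi, params.affected_ind, params.affected_dep
    pi = proportion_independent(crl, params.unaffected_prop)
    return pi, params.unaffected_ind, params.unaffected_dep


def nt_density(nt, crl, status, params: MixtureModelParams):
    """Mixture density of NT (per mm) at the given CRL and status."""
    nt = _check_nt(nt)
    crl = _check_crl(crl)
    pi, ind, dep = _status_components(status, params, crl)
    return pi * ind_pdf(nt, ind) + (1.0 - pi) * dep_pdf(nt, crl, dep)


def nt_cdf(nt, crl, status, params: MixtureModelParams):
    """Mixture CDF of NT at the given CRL and status."""
    nt = _check_nt(nt)
    crl = _check_crl(crl)
    pi, ind, dep = _status_components(status, params, crl)
    return pi * ind_cdf(nt, ind) + (1.0 - pi) * dep_cdf(nt, crl, dep)


def nt_component_ppf(u, crl, status, params: MixtureModelParams, independent: bool):
    """Quantile function of a single mixture component (used by the sampler)."""
    crl = _check_crl(crl)
    _, ind, dep = _status_components(status, params, crl)
    if independent:
        return ind_ppf(u, ind)
    return dep_ppf(u, crl, dep)


def support_upper(params: MixtureModelParams, crl) -> float:
    """Practical upper bound of the NT support at the given CRL.

    Taken as the larger of mu + 10*sigma over the independent components and
    10**(m(crl) + 8*sigma) for the dependent component.
    """
    crl = np.max(np.asarray(crl, dtype=float))
    cands = [
        params.unaffected_ind.mu + 10.0 * params.unaffected_ind.sigma,
        params.affected_ind.mu + 10.0 * params.affected_ind.sigma,
        10.0
        ** (
            float(mean_log_nt_dependent(crl, params.unaffected_dep))
            + 8.0 * params.unaffected_dep.sigma
        ),
    ]
    return max(cands)


def likelihood_ratio_mixture(nt, crl, params: MixtureModelParams, median_curve=None):
    """Affected/unaffected mixture density ratio at the truncated NT.

    The observed NT is clamped to the truncation limits first (limits on the
    MoM scale require a ``median_curve`` to convert them to mm at each CRL),
    so the likelihood ratio is constant beyond the limits.
    """
    nt = _check_nt(nt)
    crl = _check_crl(crl)
    trunc = params.truncation
    if trunc.scale == "mm":
        nt = trunc.clamp(nt)
    else:
        if median_curve is None:
            raise ValueError("MoM-scale truncation limits require a median_curve")
        med = median_curve(crl)
        nt = np.clip(nt, trunc.lower * med, trunc.upper * med)
    num = nt_density(nt, crl, Status.AFFECTED, params)
    den = nt_density(nt, crl, Status.UNAFFECTED, params)
    if np.any(den <= 0) or np.any(~np.isfinite(den)):
        raise FloatingPointError("unaffected mixture density vanished or overflowed")
    return num / den
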