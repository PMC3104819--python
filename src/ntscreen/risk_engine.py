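"""Posterior Down's syndrome risk from a maternal-age prior and a likelihood
ratio, reported in the screening programme's "1 in n" convention."""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgeRiskCurve",
    "RiskResult",
    "prior_risk",
    "posterior_probability",
    "posterior_risk",
    "format_one_in_n",
    "parse_one_in_n",
]

AGE_MIN = 15.0
AGE_MAX = 50.0


class AgeRiskCurve:
    """Maternal-age-specific prior risk of a Down's syndrome pregnancy.

    Either a lookup table (age -> probability, piecewise-linear between rows,
    constant outside or with a single row) or a parametric exponential-plus-
    baseline regression of the kind used in screening programmes:
    ``p(age) = base + exp(intercept + slope * age)``.
    """

    def __init__(self, ages=None, risks=None, *, base=None, intercept=None, slope=None):
        if ages is not None:
            ages = np.asarray(ages, dtype=float)
            risks = np.asarray(risks, dtype=float)
            if ages.size == 0:
                raise ValueError("age-risk table is empty")
            order = np.argsort(ages)
            self.ages, self.risks = ages[order], risks[order]
            if np.any((self.risks <= 0) | (self.risks >= 1)):
                raise ValueError("age-risk probabilities must lie in (0, 1)")
            if np.any(np.diff(self.risks) < 0):
                raise ValueError("age-risk table must be nondecreasing with age")
            self._parametric = None
        else:
            if None in (base, intercept, slope):
                raise ValueError("parametric curve needs base, intercept and slope")
            self._parametric = (float(base), float(intercept), float(slope))
            self.ages = self.risks = None

    @classmethod
    def from_table(cls, ages, risks) -> "AgeRiskCurve":
        return cls(ages=ages, risks=risks)

    @classmethod
    def from_regression(cls, base: float, intercept: float, slope: float) -> "AgeRiskCurve":
        return cls(base=base, intercept=intercept, slope=slope)

    @classmethod
    def constant(cls, p: float) -> "AgeRiskCurve":
        """Flat prior, e.g. the overall prevalence of a study cohort."""
        return cls(ages=[30.0], risks=[p])

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        if np.any((age < AGE_MIN) | (age > AGE_MAX)):
            raise ValueError(f"maternal age must lie in [{AGE_MIN:g}, {AGE_MAX:g}] years")
        if self._parametric is not None:
            base, intercept, slope = self._parametric
            p = base + np.exp(intercept + slope * age)
        elif self.ages.size == 1:
            p = np.full_like(age, self.risks[0])
        else:
            p = np.interp(age, self.ages, self.risks)
        return p if age.ndim else float(p)


@dataclass(frozen=True)
class RiskResult:
    """Prior, likelihood ratio and posterior risk for one pregnancy."""

    prior: float
    lr: float
    posterior: float

    @property
    def one_in_n(self) -> float:
        return 1.0 / self.posterior

    @property
    def one_in_n_text(self) -> str:
        return format_one_in_n(self.posterior)


def prior_risk(age, curve: AgeRiskCurve):
    """Prior Down's syndrome probability at the given maternal age."""
    return curve(age)


def posterior_probability(prior, lr):
    """Posterior probability via odds: posterior odds = prior odds * LR."""
    prior = np.asarray(prior, dtype=float)
    lr = np.asarray(lr, dtype=float)
    if np.any((prior <= 0) | (prior >= 1)):
        raise ValueError("prior must lie strictly in (0, 1)")
    if np.any(lr <= 0):
        raise ValueError("likelihood ratio must be positive")
    odds = lr * prior / (1.0 - prior)
    post = odds / (1.0 + odds)
    return post if post.ndim else float(post)


def posterior_risk(prior: float, lr: float) -> RiskResult:
    """Combine a prior probability with a likelihood ratio into a RiskResult."""
    return RiskResult(prior=float(prior), lr=float(lr),
                      posterior=posterior_probability(prior, lr))


def format_one_in_n(p: float) -> str:
    """Render a probability as "1 in n": one decimal for n < 10, else integer."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"probability must lie in (0, 1), got {p}")
    n = 1.0 / p
    if n < 10.0:
        return f"1 in {n:.1f}"
    return f"1 in {round(n):d}"


_ONE_IN_N = re.compile(r"^\s*1\s+in\s+([0-9]+(?:\.[0-9]+)?)\s*$")


def parse_one_in_n(text: str) -> float:
    """Inverse of :func:`format_one_in_n` (up to formatting precision)."""
    m = _ONE_IN_N.match(text)
    if not m:
        raise ValueError(f"cannot parse {text!r} as '1 in n'")
    return 1.0 / float(m.group(1))
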