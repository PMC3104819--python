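"""Maximum-likelihood fitting of the NT mixture model by EM.

Affected and unaffected pregnancies are fitted separately.  The unaffected
fit estimates the log-quadratic mean curve and SD of the CRL-dependent
component, the mean/SD of the CRL-independent component and the two endpoint
anchors of the linear mixing-proportion curve.  The affected fit keeps the
CRL-dependent component tied to the unaffected one and estimates the
independent component's mean/SD plus a constant mixing proportion.

Each EM iteration alternates responsibilities with exact (or numerically
maximised) weighted component updates, so the log-likelihood is
nondecreasing; multiple random restarts guard against local maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .mixture_model import (
    CRL_MAX,
    CRL_MIN,
    DependentComponentParams,
    IndependentComponentParams,
    MixtureModelParams,
    ProportionCurve,
    Status,
    _dep_logpdf,
    nt_density,
)

__all__ = ["FitSettings", "FitResult", "EstimationError", "log_likelihood",
           "fit_mixture", "fit_cohort"]

logger = logging.getLogger(__name__)

_PROP_LO, _PROP_HI = 1e-4, 0.8  # proportion bounds during fitting


class EstimationError(RuntimeError):
    """All EM restarts diverged or hit a degenerate boundary."""


@dataclass(frozen=True)
class FitSettings:
    max_iterations: int = 500
    tolerance: float = 1e-7
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class FitResult:
    params: MixtureModelParams
    log_likelihood: float
    converged: bool
    n_iterations: int
    restart_index: int


def _extract_arrays(cohort, status: Status):
    status = Status(status)
    if "status" in cohort.columns:
        sub = cohort[cohort["status"] == status.value]
    else:
        sub = cohort
    if len(sub) == 0:
        raise ValueError(f"no {status.value} records in cohort")
    return sub["nt_mm"].to_numpy(float), sub["crl_mm"].to_numpy(float)


def log_likelihood(params: MixtureModelParams, cohort, status: Status) -> float:
    """Sum of log mixture densities over the given status's records."""
    nt, crl = _extract_arrays(cohort, status)
    return float(np.sum(np.log(nt_density(nt, crl, status, params))))


def _ind_logpdf(nt, mu, sigma):
    # zero-truncated Gaussian in mm
    z = (nt - mu) / sigma
    log_mass = stats.norm.logsf(-mu / sigma)
    return stats.norm.logpdf(z) - np.log(sigma) - log_mass


def _weighted_truncnorm_mle(nt, w, mu0, sigma0, sigma_floor):
    """Maximise the w-weighted zero-truncated-normal log-likelihood.

    The objective depends on the data only through the weighted sums
    (sum w, sum w*x, sum w*x^2), so each optimiser evaluation is O(1).
    """
    s0 = float(w.sum())
    if s0 <= 0:
        return mu0, sigma0
    s1 = float(np.dot(w, nt))
    s2 = float(np.dot(w, nt * nt))

    def neg(theta):
        mu, log_sig = theta
        sig = max(np.exp(log_sig), sigma_floor)
        sq = s2 - 2.0 * mu * s1 + mu * mu * s0
        return (0.5 * sq / sig**2 + s0 * np.log(sig)
                + s0 * stats.norm.logsf(-mu / sig)) / s0

    res = optimize.minimize(neg, x0=[mu0, np.log(sigma0)], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400})
    mu, log_sig = res.x
    return float(mu), float(max(np.exp(log_sig), sigma_floor))


def _fit_prop_anchors(r, t, p45_0, p84_0):
    """Maximise the Bernoulli responsibility likelihood over the two anchors.

    The proportion is linear in the rescaled CRL ``t`` in [0, 1].
    """

    def neg(theta):
        p = theta[0] + t * (theta[1] - theta[0])
        p = np.clip(p, _PROP_LO, 1.0 - _PROP_LO)
        val = -float(np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p)))
        g = -(r / p - (1.0 - r) / (1.0 - p))
        return val, np.array([np.dot(g, 1.0 - t), np.dot(g, t)])

    x0 = [np.clip(p45_0, _PROP_LO, _PROP_HI), np.clip(p84_0, _PROP_LO, _PROP_HI)]
    res = optimize.minimize(neg, x0=x0, method="L-BFGS-B", jac=True,
                            bounds=[(_PROP_LO, _PROP_HI)] * 2)
    return float(res.x[0]), float(res.x[1])


def _responsibilities(log_f_ind, log_f_dep, pi):
    pi = np.clip(pi, 1e-12, 1.0 - 1e-12)
    s = np.log(pi) + log_f_ind - np.log1p(-pi) - log_f_dep
    return 1.0 / (1.0 + np.exp(-s))


def _em_unaffected(nt, crl, settings: FitSettings, rng):
    n = nt.size
    log_nt = np.log10(nt)
    t = (crl - CRL_MIN) / (CRL_MAX - CRL_MIN)
    X = np.column_stack([np.ones(n), crl, crl * crl])
    sigma_floor_dep = 1e-4 * float(np.std(log_nt))
    sigma_floor_ind = 1e-4 * float(np.std(nt))

    # init: quadratic fit of log10 NT on CRL; independent component seeded in
    # the upper tail; anchors at a common random proportion
    coef, *_ = np.linalg.lstsq(X, log_nt, rcond=None)
    resid = log_nt - X @ coef
    sig_dep = max(float(np.std(resid)), sigma_floor_dep)
    pi0 = rng.uniform(0.02, 0.3)
    mu_ind = float(np.quantile(nt, rng.uniform(0.7, 0.98)))
    sig_ind = max(float(np.std(nt)) * rng.uniform(0.5, 1.5), sigma_floor_ind)
    p45, p84 = pi0, pi0

    ll_prev = -np.inf
    for it in range(1, settings.max_iterations + 1):
        pi = np.clip(p45 + t * (p84 - p45), _PROP_LO, 1 - _PROP_LO)
        dep = DependentComponentParams(coef[0], coef[1], coef[2], sig_dep)
        log_f_dep = _dep_logpdf(nt, crl, dep)
        log_f_ind = _ind_logpdf(nt, mu_ind, sig_ind)
        r = _responsibilities(log_f_ind, log_f_dep, pi)

        # M-step: weighted quadratic regression for the dependent component
        w = 1.0 - r
        wsum = w.sum()
        if wsum < 10 or r.sum() < 1e-6:
            return None  # degenerate: one component vanished
        Xw = X * w[:, None]
        coef = np.linalg.solve(X.T @ Xw, Xw.T @ log_nt)
        resid = log_nt - X @ coef
        sig_dep = max(float(np.sqrt((w * resid**2).sum() / wsum)), sigma_floor_dep)
        # weighted truncated-normal update for the independent component
        mu_ind, sig_ind = _weighted_truncnorm_mle(nt, r, mu_ind, sig_ind, sigma_floor_ind)
        # proportion anchors from responsibilities
        p45, p84 = _fit_prop_anchors(r, t, p45, p84)
        if p84 > p45:  # enforce the declining-proportion convention
            p45 = p84 = 0.5 * (p45 + p84)

        pi = np.clip(p45 + t * (p84 - p45), _PROP_LO, 1 - _PROP_LO)
        dep = DependentComponentParams(coef[0], coef[1], coef[2], sig_dep)
        log_mix = np.logaddexp(
            np.log(pi) + _ind_logpdf(nt, mu_ind, sig_ind),
            np.log1p(-pi) + _dep_logpdf(nt, crl, dep),
        )
        ll = float(log_mix.sum())
        if not np.isfinite(ll):
            return None
        if abs(ll - ll_prev) < settings.tolerance:
            return dict(dep=dep, ind=IndependentComponentParams(mu_ind, sig_ind),
                        prop=ProportionCurve(p45, p84), ll=ll, converged=True, n_iter=it)
        ll_prev = ll
    return dict(dep=dep, ind=IndependentComponentParams(mu_ind, sig_ind),
                prop=ProportionCurve(p45, p84), ll=ll, converged=False,
                n_iter=settings.max_iterations)


def _em_affected(nt, crl, dep: DependentComponentParams, settings: FitSettings, rng):
    sigma_floor_ind = 1e-4 * float(np.std(nt))
    log_f_dep = _dep_logpdf(nt, crl, dep)  # tied component: fixed throughout

    pi = rng.uniform(0.6, 0.98)
    mu_ind = float(np.median(nt))
    sig_ind = max(float(np.std(nt)), sigma_floor_ind)

    ll_prev = -np.inf
    for it in range(1, settings.max_iterations + 1):
        log_f_ind = _ind_logpdf(nt, mu_ind, sig_ind)
        r = _responsibilities(log_f_ind, log_f_dep, pi)
        if r.sum() < 1e-6 or (1.0 - r).sum() < 1e-6:
            return None
        mu_ind, sig_ind = _weighted_truncnorm_mle(nt, r, mu_ind, sig_ind, sigma_floor_ind)
        pi = float(np.clip(r.mean(), 1e-6, 1.0 - 1e-6))
        log_mix = np.logaddexp(np.log(pi) + _ind_logpdf(nt, mu_ind, sig_ind),
                               np.log1p(-pi) + log_f_dep)
        ll = float(log_mix.sum())
        if not np.isfinite(ll):
            return None
        if abs(ll - ll_prev) < settings.tolerance:
            return dict(ind=IndependentComponentParams(mu_ind, sig_ind), pi=pi,
                        ll=ll, converged=True, n_iter=it)
        ll_prev = ll
    return dict(ind=IndependentComponentParams(mu_ind, sig_ind), pi=pi, ll=ll,
                converged=False, n_iter=settings.max_iterations)


def fit_mixture(cohort, status: Status, settings: FitSettings,
                template: MixtureModelParams) -> FitResult:
    """Fit one status's mixture parameters by EM with random restarts.

    ``template`` supplies the blocks not estimated in this fit (the other
    status's parameters and the truncation limits); for an affected fit it
    also provides the CRL-dependent component, which is held fixed.
    Returns the best restart by final log-likelihood.
    """
    status = Status(status)
    nt, crl = _extract_arrays(cohort, status)
    if nt.size < 50:
        raise ValueError(f"need at least 50 records to fit, got {nt.size}")

    best = None
    ss = np.random.SeedSequence(settings.seed)
    for idx, child in enumerate(ss.spawn(settings.n_restarts)):
        rng = np.random.default_rng(child)
        if status is Status.UNAFFECTED:
            out = _em_unaffected(nt, crl, settings, rng)
        else:
            out = _em_affected(nt, crl, template.unaffected_dep, settings, rng)
        if out is None:
            logger.debug("restart %d diverged", idx)
            continue
        if best is None or out["ll"] > best[1]["ll"]:
            best = (idx, out)
    if best is None:
        raise EstimationError(
            f"all {settings.n_restarts} EM restarts diverged for status {status.value} "
            f"(n={nt.size}); check the data scale or loosen the settings"
        )
    idx, out = best
    if status is Status.UNAFFECTED:
        params = template.with_(unaffected_dep=out["dep"], unaffected_ind=out["ind"],
                                unaffected_prop=out["prop"])
    else:
        params = template.with_(affected_ind=out["ind"], affected_prop_ind=out["pi"])
    return FitResult(params=params, log_likelihood=out["ll"], converged=out["converged"],
                     n_iterations=out["n_iter"], restart_index=idx)


def fit_cohort(cohort, settings: FitSettings,
               template: MixtureModelParams) -> FitResult:
    """Fit both statuses: unaffected first, then affected with the
    CRL-dependent component tied to the unaffected fit."""
    unaff = fit_mixture(cohort, Status.UNAFFECTED, settings, template)
    aff = fit_mixture(cohort, Status.AFFECTED, settings, unaff.params)
    return FitResult(params=aff.params,
                     log_likelihood=unaff.log_likelihood + aff.log_likelihood,
                     converged=unaff.converged and aff.converged,
                     n_iterations=max(unaff.n_iterations, aff.n_iterations),
                     restart_index=aff.restart_index)
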