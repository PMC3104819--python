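"""Synthetic screening cohorts with the generative structure the risk models
assume.

Each simulated pregnancy gets a CRL, a maternal age, a mixture-component
membership and an NT drawn from that component, conditional on its status.
Cohort sizes default to 104 Down's syndrome and 22,284 unaffected
pregnancies with CRL between 45 and 84 mm.  Sampling uses independent named
substreams of a single master seed (CRL / age / component / NT, per status),
so enlarging a cohort leaves the records already drawn unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture_model import (
    CRL_MAX,
    CRL_MIN,
    MixtureModelParams,
    Status,
    nt_component_ppf,
    proportion_independent,
)

__all__ = ["PregnancyRecord", "CohortSpec", "simulate_cohort", "truncate_cohort",
           "COHORT_COLUMNS"]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["id", "crl_mm", "nt_mm", "maternal_age_years", "status"]

# substream order under the master seed; fixed so streams are stable
_STREAMS = ["crl", "age", "component", "nt"]


@dataclass(frozen=True)
class PregnancyRecord:
    """One screened pregnancy.

    ``component`` records which mixture component generated the NT
    ('independent' or 'dependent'); it is truth-tracking metadata kept out of
    blinded outputs.
    """

    id: str
    crl_mm: float
    nt_mm: float
    maternal_age_years: float
    status: Status
    component: str | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    CRL is uniform over [45, 84] mm and maternal age triangular on [15, 45]
    peaking at 29 by default — stand-ins, since the source programme's CRL
    and age distributions are unpublished.  Affected and unaffected
    pregnancies share both distributions (no confounding by construction).
    """

    params: MixtureModelParams
    n_affected: int = 104
    n_unaffected: int = 22284
    seed: int = 0
    crl_distribution: str = "uniform"
    age_distribution: str = "triangular"
    age_range: tuple = (15.0, 45.0)
    age_mode: float = 29.0

    def __post_init__(self):
        if self.n_affected < 0 or self.n_unaffected < 0:
            raise ValueError("cohort counts must be nonnegative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def _status_streams(seed: int, status: Status) -> dict:
    """Independent generators per (status, variable) pair."""
    root = np.random.SeedSequence(seed)
    aff, unaff = root.spawn(2)
    branch = aff if status is Status.AFFECTED else unaff
    children = branch.spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _draw_crl(rng, n, spec: CohortSpec):
    if spec.crl_distribution != "uniform":
        raise ValueError(f"unknown CRL distribution {spec.crl_distribution!r}")
    return rng.uniform(CRL_MIN, CRL_MAX, size=n)


def _draw_age(rng, n, spec: CohortSpec):
    if spec.age_distribution != "triangular":
        raise ValueError(f"unknown age distribution {spec.age_distribution!r}")
    lo, hi = spec.age_range
    return rng.triangular(lo, spec.age_mode, hi, size=n)


def _simulate_status(spec: CohortSpec, status: Status, n: int) -> pd.DataFrame:
    rngs = _status_streams(spec.seed, status)
    crl = _draw_crl(rngs["crl"], n, spec)
    age = _draw_age(rngs["age"], n, spec)
    if status is Status.AFFECTED:
        p_ind = np.full(n, spec.params.affected_prop_ind)
    else:
        p_ind = proportion_independent(crl, spec.params.unaffected_prop)
    is_ind = rngs["component"].random(n) < p_ind
    # inverse-CDF draw from the selected component keeps the NT stream aligned
    u = rngs["nt"].random(n)
    nt = np.empty(n)
    if is_ind.any():
        nt[is_ind] = nt_component_ppf(u[is_ind], crl[is_ind], status, spec.params,
                                      independent=True)
    if (~is_ind).any():
        nt[~is_ind] = nt_component_ppf(u[~is_ind], crl[~is_ind], status, spec.params,
                                       independent=False)
    prefix = "DS" if status is Status.AFFECTED else "UN"
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i:06d}" for i in range(n)],
            "crl_mm": crl,
            "nt_mm": nt,
            "maternal_age_years": age,
            "status": status.value,
            "component": np.where(is_ind, "independent", "dependent"),
        }
    )


def simulate_cohort(spec: CohortSpec, with_truth: bool = True) -> pd.DataFrame:
    """Simulate a labelled screening cohort; deterministic given the seed.

    Returns a DataFrame with columns id, crl_mm, nt_mm, maternal_age_years,
    status (and the truth-tracking ``component`` column unless
    ``with_truth=False``).
    """
    frames = [
        _simulate_status(spec, Status.AFFECTED, spec.n_affected),
        _simulate_status(spec, Status.UNAFFECTED, spec.n_unaffected),
    ]
    cohort = pd.concat(frames, ignore_index=True)
    if not with_truth:
        cohort = cohort[COHORT_COLUMNS]
    return cohort


def truncate_cohort(records: pd.DataFrame, crl_min: float = CRL_MIN) -> pd.DataFrame:
    """Drop records with CRL below the cutoff (default 45 mm), logging counts.

    Mirrors the screening-programme practice of excluding pregnancies dated
    below the range over which the model is parameterised.  Idempotent.
    """
    keep = records["crl_mm"] >= crl_min
    n_removed = int((~keep).sum())
    if n_removed:
        by_status = records.loc[~keep, "status"].value_counts().to_dict()
        logger.info("excluded %d records with CRL < %g mm (%s)", n_removed, crl_min, by_status)
    return records.loc[keep].reset_index(drop=True)
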