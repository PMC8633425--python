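"""Normative W-score modelling of regional deformation.

The W-score standardises a participant's deformation value against what a
healthy person of the same age and sex is expected to show:

    W_i = (DBM_i - (beta1 * age + beta2 * sex + beta3)) / SD_i

where the betas come from an ordinary least-squares fit on baseline healthy
controls, region by region, and SD_i is the standard deviation of the
control residuals (denominator n - 3, unbiased under the three-parameter
model).  Negative W means atrophy.  W is invariant to a common rescaling of
the deformation unit because the residual SD rescales with it.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import CohortTable, WScoreModel

logger = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12


def fit_wscore_model(hc_baseline: CohortTable) -> WScoreModel:
    """Fit per-region OLS of deformation on (age, sex, intercept).

    Expects healthy-control baseline rows only; requires at least 4
    subjects and both sexes (otherwise the sex coefficient is not
    estimable).  Raises if any region has (numerically) zero residual SD,
    which indicates degenerate control data.
    """
    demo = hc_baseline.demographics
    if not (demo["group"] == "HC").all() or not (demo["session"] == "baseline").all():
        raise ValueError("fit_wscore_model expects HC baseline rows only")
    n = hc_baseline.n_rows
    if n < 4:
        raise ValueError("need at least 4 controls to fit the normative model")
    sexes = demo["sex"].to_numpy(dtype=float)
    if len(np.unique(sexes)) < 2:
        raise ValueError("single-sex control cohort: sex coefficient inestimable")
    ages = demo["age"].to_numpy(dtype=float)
    x = np.column_stack([ages, sexes, np.ones(n)])
    y = hc_baseline.values
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    resid_sd = np.sqrt((resid**2).sum(axis=0) / (n - 3))
    if np.any(resid_sd < _DEGENERATE_TOL):
        raise ValueError("degenerate control data: zero residual SD in some region")
    return WScoreModel(
        region_ids=hc_baseline.region_ids,
        beta_age=beta[0],
        beta_sex=beta[1],
        beta_intercept=beta[2],
        resid_sd=resid_sd,
        n_controls=n,
    )


def compute_wscores(model: WScoreModel, age: float, sex: int, values: np.ndarray) -> np.ndarray:
    """W-score map for one scan: (value - expected) / residual SD per region."""
    values = np.asarray(values, dtype=float)
    if values.shape != model.region_ids.shape:
        raise ValueError("value vector length must match model regions")
    if not 0 <= age <= 120:
        logger.warning("age %.1f outside [0, 120]: extrapolating the normative model", age)
    expected = model.beta_age * age + model.beta_sex * sex + model.beta_intercept
    return (values - expected) / model.resid_sd


def wscore_cohort(model: WScoreModel, cohort: CohortTable) -> CohortTable:
    """W-score every scan of a cohort (vectorised across rows)."""
    if list(cohort.region_ids) != list(model.region_ids):
        raise ValueError("cohort regions do not match model regions")
    demo = cohort.demographics
    ages = demo["age"].to_numpy(dtype=float)[:, None]
    sexes = demo["sex"].to_numpy(dtype=float)[:, None]
    expected = model.beta_age * ages + model.beta_sex * sexes + model.beta_intercept
    w = (cohort.values - expected) / model.resid_sd
    return CohortTable(demo.copy(), w, cohort.region_ids)
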