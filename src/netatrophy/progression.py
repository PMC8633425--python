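"""Atrophy-progression maps, group tests and the clinical battery.

The progression score of a region is the *decrease* in W-score from
baseline to a follow-up, ``score = -(W_followup - W_baseline)``, so that
positive values mean atrophy accrued.  Group inference uses a one-way
repeated-measures ANOVA across sessions (subjects as blocks) with
family-wise error control by max-statistic permutation of session labels
within subjects; cortical-type contrasts use a one-way ANOVA over regions;
clinical associations use partial Spearman correlations with FDR control.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SESSIONS, CohortTable, as_rng

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# progression maps
# ---------------------------------------------------------------------------

def progression_map(
    w_baseline: np.ndarray,
    w_followup: np.ndarray,
    aggregate: str = "group-mean",
    subjects_baseline=None,
    subjects_followup=None,
) -> np.ndarray:
    """Per-subject or group-mean atrophy-progression score, ``-(W_fu - W_bl)``."""
    w_baseline = np.atleast_2d(np.asarray(w_baseline, dtype=float))
    w_followup = np.atleast_2d(np.asarray(w_followup, dtype=float))
    if subjects_baseline is not None or subjects_followup is not None:
        if list(subjects_baseline) != list(subjects_followup):
            raise ValueError("baseline and follow-up subject sets differ")
    if w_baseline.shape != w_followup.shape:
        raise ValueError("baseline and follow-up W maps must have the same shape")
    score = -(w_followup - w_baseline)
    if aggregate == "group-mean":
        return score.mean(axis=0)
    if aggregate == "subject":
        return score
    raise ValueError("aggregate must be 'subject' or 'group-mean'")


def stack_sessions(
    w_cohort: CohortTable, group: str = "PD", sessions: tuple[str, ...] = SESSIONS
) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Complete-case (subject, session, region) array for one group.

    Returns subjects with a scan at every requested session, the
    ``(n_subjects, n_sessions, n_regions)`` value array in session order,
    and one demographics row per subject (from the first session).
    """
    sub = w_cohort.subset(group=group)
    demo = sub.demographics
    per_session = {}
    for s in sessions:
        mask = (demo["session"] == s).to_numpy()
        per_session[s] = dict(zip(demo["subject_id"][mask], np.flatnonzero(mask)))
    subjects = sorted(set.intersection(*(set(d) for d in per_session.values())))
    if not subjects:
        raise ValueError("no subject has scans at every requested session")
    y = np.stack(
        [sub.values[[per_session[s][subj] for subj in subjects]] for s in sessions], axis=1
    )
    first = sessions[0]
    demo_rows = demo.iloc[[per_session[first][subj] for subj in subjects]].reset_index(drop=True)
    return subjects, y, demo_rows


# ---------------------------------------------------------------------------
# repeated-measures F machinery
# ---------------------------------------------------------------------------

def _rm_f_stats(y: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F per region; ``y`` is (n, T, R)."""
    n, t, _ = y.shape
    gm = y.mean(axis=(0, 1))
    subj = y.mean(axis=1)
    time = y.mean(axis=0)
    ss_tot = ((y - gm) ** 2).sum(axis=(0, 1))
    ss_subj = t * ((subj - gm) ** 2).sum(axis=0)
    ss_time = n * ((time - gm) ** 2).sum(axis=0)
    ss_err = np.maximum(ss_tot - ss_subj - ss_time, 0.0)
    ms_time = ss_time / (t - 1)
    ms_err = ss_err / ((n - 1) * (t - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_err > 0, ms_time / np.where(ms_err > 0, ms_err, 1.0), 0.0)
    return f


def _residualize_covariates(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Remove the between-subject covariate component from (n, T, R) data.

    The covariates (sex, site) are constant within subject, so their
    additive effect is estimated from the subject session-means and the
    same centred-covariate component is subtracted from every session of a
    subject.  Subtracting a session-constant adjustment keeps the data
    exactly exchangeable across sessions within subject (the permutation
    null stays exact) while removing covariate-related between-subject
    variance.
    """
    covs = design[:, 1:]
    if covs.shape[1] == 0:
        return y
    subj_means = y.mean(axis=1)  # (n, R)
    beta, *_ = np.linalg.lstsq(design, subj_means, rcond=None)
    centred = covs - covs.mean(axis=0)
    adjust = centred @ beta[1:]  # (n, R), same for every session
    return y - adjust[:, None, :]


def _covariate_design(sex: np.ndarray, site: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(sex)), np.asarray(sex, dtype=float)]
    if site is not None:
        site = np.asarray(site, dtype=object)
        levels, counts = np.unique(site, return_counts=True)
        keep = [l for l, c in zip(levels, counts) if c >= 2]
        dropped = [l for l, c in zip(levels, counts) if c < 2]
        if dropped:
            logger.warning("site level(s) with a single subject dropped: %s", dropped)
        for level in keep[1:]:  # reference = first retained level
            cols.append((site == level).astype(float))
    return np.column_stack(cols)


@dataclass
class RegionalTestResult:
    """Region-wise repeated-measures test with FWE/FDR adjustments."""

    table: pd.DataFrame  # region, F, p_param, p_fdr, p_fwe, sig flags
    posthoc: pd.DataFrame  # session, region, t, p_one_tailed
    n_subjects: int
    n_permutations: int
    alpha: float


def regional_progression_test(
    y: np.ndarray,
    sex: np.ndarray,
    site: np.ndarray | None = None,
    region_ids=None,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
    sessions: tuple[str, ...] = SESSIONS,
) -> RegionalTestResult:
    """Covariate-adjusted repeated-measures F per region with permutation FWE.

    ``y`` is the (subjects x sessions x regions) W-score array.  Values are
    first residualised on sex and scanner site (between-subject
    covariates), then a one-way repeated-measures F across sessions is
    computed per region.  FWE control uses the max-statistic over ``n_perm``
    within-subject permutations of the session labels — exchangeable under
    the null of no time effect — and Benjamini-Hochberg FDR over the
    parametric p-values is reported alongside.  Post-hoc one-tailed paired
    contrasts compare baseline against each follow-up (direction: W
    decreases, i.e. atrophy worsens).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must be (n_subjects, n_sessions, n_regions)")
    n, t, r = y.shape
    if t < 2:
        raise ValueError("need at least 2 sessions")
    if n < 6:
        raise ValueError("need at least 6 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_rng(seed)
    if region_ids is None:
        region_ids = [f"r{i}" for i in range(r)]

    design = _covariate_design(np.asarray(sex, dtype=float), site)
    y_res = _residualize_covariates(y, design)

    f_obs = _rm_f_stats(y_res)
    p_param = scipy.stats.f.sf(f_obs, t - 1, (n - 1) * (t - 1))

    # invariants under within-subject session permutation
    gm = y_res.mean(axis=(0, 1))
    ss_tot = ((y_res - gm) ** 2).sum(axis=(0, 1))
    ss_subj = t * ((y_res.mean(axis=1) - gm) ** 2).sum(axis=0)
    max_f = np.empty(n_perm)
    chunk = max(1, int(2e7 // (n * t * r)))
    done = 0
    rows_idx = np.arange(n)[None, :, None]
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, n, t)), axis=2)
        yg = y_res[rows_idx, perm]  # (m, n, t, r)
        tm = yg.mean(axis=1)  # (m, t, r)
        ss_time_p = n * ((tm - gm) ** 2).sum(axis=1)
        ss_err_p = np.maximum(ss_tot - ss_subj - ss_time_p, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_time_p / (t - 1)) / np.where(
                ss_err_p > 0, ss_err_p / ((n - 1) * (t - 1)), np.inf
            )
        max_f[done : done + m] = f_p.max(axis=1)
        done += m
    p_fwe = (1 + (max_f[None, :] >= f_obs[:, None]).sum(axis=1)) / (1 + n_perm)
    p_fdr = multipletests(p_param, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "region": list(region_ids),
            "F": f_obs,
            "p_param": p_param,
            "p_fdr": p_fdr,
            "p_fwe": p_fwe,
            "sig_fwe": p_fwe < alpha,
            "sig_fdr": p_fdr < alpha,
        }
    )

    posthoc_rows = []
    for k in range(1, t):
        d = y_res[:, k, :] - y_res[:, 0, :]
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
        p_one = scipy.stats.t.cdf(tstat, n - 1)  # lower tail: W declines
        for j in range(r):
            posthoc_rows.append(
                {
                    "session": sessions[k] if k < len(sessions) else f"s{k}",
                    "region": region_ids[j],
                    "t": tstat[j],
                    "p_one_tailed": p_one[j],
                }
            )
    return RegionalTestResult(
        table=table,
        posthoc=pd.DataFrame(posthoc_rows),
        n_subjects=n,
        n_permutations=n_perm,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# cortical-type ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f: float
    p: float
    means: pd.Series
    pairwise: pd.DataFrame  # class_a, class_b, t, p_raw, p_bonf


def cortical_type_anova(values: np.ndarray, types: np.ndarray, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of a regional map across cortical-type classes.

    Regions are the observations.  Pairwise two-sample t-tests between
    classes are Bonferroni-adjusted for the number of comparisons.
    """
    values = np.asarray(values, dtype=float)
    types = np.asarray(types, dtype=object)
    classes = list(pd.unique(types))
    if len(classes) < 2:
        raise ValueError("need at least 2 cortical-type classes")
    groups = [values[types == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every class needs at least 2 regions")
    if all(np.allclose(g, g[0]) for g in groups):
        raise ValueError("zero within-class variance in all classes")
    f, p = scipy.stats.f_oneway(*groups)
    means = pd.Series({c: g.mean() for c, g in zip(classes, groups)})
    pairs = list(itertools.combinations(range(len(classes)), 2))
    rows = []
    for i, j in pairs:
        t, praw = scipy.stats.ttest_ind(groups[i], groups[j])
        rows.append(
            {
                "class_a": classes[i],
                "class_b": classes[j],
                "t": float(t),
                "p_raw": float(praw),
                "p_bonf": min(1.0, float(praw) * len(pairs)),
            }
        )
    return AnovaResult(f=float(f), p=float(p), means=means, pairwise=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# partial Spearman battery
# ---------------------------------------------------------------------------

def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks for ties); x and y
    are then residualised on the ranked covariates (plus intercept) and the
    Pearson correlation of the residuals is the partial rho.  The p-value
    uses the t approximation with ``df = n - 2 - k``.  Without covariates
    this is exactly the ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate length must match x/y")
        k = cov.shape[1]
        rcov = np.column_stack(
            [scipy.stats.rankdata(cov[:, j]) for j in range(k)] + [np.ones(n)]
        )
        rx = rx - rcov @ np.linalg.lstsq(rcov, rx, rcond=None)[0]
        ry = ry - rcov @ np.linalg.lstsq(rcov, ry, rcond=None)[0]
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero rank variance after residualisation")
    rho = float((rx * ry).sum() / denom)
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for the given covariates")
    rho_c = np.clip(rho, -1.0, 1.0)
    if abs(rho_c) >= 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return rho, p


def partial_spearman_battery(
    xs: pd.DataFrame,
    ys: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_n: int = 10,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """All (x, y) pairwise partial Spearman correlations with BH-FDR.

    Complete cases are taken per pair (including covariates); pairs with
    fewer than ``min_n`` complete cases are an error.
    """
    rows = []
    for xname in xs.columns:
        for yname in ys.columns:
            frame = pd.DataFrame({"_x": xs[xname], "_y": ys[yname]})
            if covariates is not None:
                for c in covariates.columns:
                    frame[c] = covariates[c]
            frame = frame.dropna()
            if len(frame) < min_n:
                raise ValueError(
                    f"fewer than {min_n} complete cases for pair ({xname}, {yname})"
                )
            cov = None
            if covariates is not None and len(covariates.columns):
                cov = frame[list(covariates.columns)].to_numpy()
            rho, p = partial_spearman(frame["_x"].to_numpy(), frame["_y"].to_numpy(), cov)
            rows.append({"x": xname, "y": yname, "n": len(frame), "rho": rho, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = p_adjust(out["p_raw"].to_numpy(), "bh_fdr")
    out["sig_fdr"] = out["p_fdr"] < fdr_alpha
    return out


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

_METHODS = {"bonferroni": "bonferroni", "holm": "holm", "bh_fdr": "fdr_bh"}


def p_adjust(pvalues: np.ndarray, method: str) -> np.ndarray:
    """Adjusted p-values: Bonferroni, Bonferroni-Holm, or Benjamini-Hochberg."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=_METHODS[method])[1]


# ---------------------------------------------------------------------------
# clinical repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    f: float
    p: float
    df: tuple[int, int]
    posthoc: pd.DataFrame  # session, t, p_raw, p_holm


def rm_anova_clinical(
    data: np.ndarray, sessions: tuple[str, ...] = SESSIONS
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA of a clinical measure over sessions.

    ``data`` is (subjects x sessions), complete cases only (rows with NaN
    are dropped).  Post-hoc two-tailed paired t-tests compare baseline
    against each follow-up with Bonferroni-Holm adjustment.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_subjects, n_sessions)")
    data = data[np.isfinite(data).all(axis=1)]
    n, t = data.shape
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    f = float(_rm_f_stats(data[:, :, None])[0])
    df = (t - 1, (n - 1) * (t - 1))
    p = float(scipy.stats.f.sf(f, *df))
    rows = []
    praws = []
    for k in range(1, t):
        tstat, praw = scipy.stats.ttest_rel(data[:, k], data[:, 0])
        if not np.isfinite(tstat):  # zero-variance difference: no effect
            tstat, praw = 0.0, 1.0
        label = sessions[k] if k < len(sessions) else f"s{k}"
        rows.append({"session": label, "t": float(tstat)})
        praws.append(float(praw))
    adj = p_adjust(np.array(praws), "holm") if praws else np.array([])
    posthoc = pd.DataFrame(rows)
    posthoc["p_raw"] = praws
    posthoc["p_holm"] = adj
    return RmAnovaResult(f=f, p=p, df=df, posthoc=posthoc)
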