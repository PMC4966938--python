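"""Survival endpoints and association statistics.

Endpoints are 3-year progression-free and overall survival measured from
the start of treatment for the liver metastases; administrative censoring
is applied at the horizon (time' = min(time, 36), event only if within the
horizon). Group comparisons use Kaplan-Meier estimates, the log-rank test
of linear trend across ordered strata, and Cox proportional-hazards
regression with Wald tests (Efron tie handling via lifelines). Segment-wise
group differences use Welch t-tests with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import warnings

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AtomicSegmentMatrix

logger = logging.getLogger("methet")

DEFAULT_HORIZON = 36.0  # months


def apply_horizon(
    times: np.ndarray, events: np.ndarray, horizon: float = DEFAULT_HORIZON
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring: clamp times at the horizon, drop later events."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ValueError("negative survival times")
    return np.minimum(t, horizon), e & (t <= horizon)


def km_rate(
    times: np.ndarray,
    events: np.ndarray,
    at: float = DEFAULT_HORIZON,
    horizon: Optional[float] = DEFAULT_HORIZON,
) -> Optional[float]:
    """Product-limit survival probability at ``at`` months.

    Past the end of follow-up the estimate at the last observed time is
    carried forward (the standard product-limit convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("no subjects")
    if horizon is not None:
        t, e = apply_horizon(t, e, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    return float(kmf.predict(at))


def three_year_rate(
    times: np.ndarray,
    events: np.ndarray,
    groups: Sequence,
    horizon: float = DEFAULT_HORIZON,
) -> dict:
    """KM survival probability at the horizon per group."""
    g = np.asarray(groups)
    out = {}
    for label in pd.unique(g):
        sel = g == label
        if not sel.any():
            raise ValueError(f"empty group {label!r}")
        out[label] = km_rate(
            np.asarray(times)[sel], np.asarray(events)[sel], at=horizon,
            horizon=horizon,
        )
    return out


def logrank_trend(
    times: np.ndarray,
    events: np.ndarray,
    strata: Sequence,
    scores: Optional[Sequence[float]] = None,
    horizon: Optional[float] = None,
) -> tuple[float, float]:
    """Log-rank test of linear trend across ordered strata (1 df).

    Strata are coded by their sorted order with equally spaced scores
    0, 1, 2, ... unless ``scores`` is given. With two strata this reduces
    exactly to the ordinary log-rank test.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if horizon is not None:
        t, e = apply_horizon(t, e, horizon)
    s = np.asarray(strata)
    levels = sorted(pd.unique(s).tolist())
    if len(levels) < 2:
        raise ValueError("trend test needs at least two strata")
    for lv in levels:
        if not (s == lv).any():
            raise ValueError(f"empty stratum {lv!r}")
    if scores is None:
        scores = np.arange(len(levels), dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
        if len(scores) != len(levels):
            raise ValueError("one score per stratum required")
    gidx = np.array([levels.index(v) for v in s])

    G = len(levels)
    event_times = np.unique(t[e])
    OE = np.zeros(G)
    V = np.zeros((G, G))
    for et in event_times:
        at_risk = t >= et
        n_t = at_risk.sum()
        if n_t == 0:
            continue
        d_t = int((e & (t == et)).sum())
        n_g = np.array([(at_risk & (gidx == g)).sum() for g in range(G)], float)
        d_g = np.array([((e) & (t == et) & (gidx == g)).sum() for g in range(G)], float)
        p_g = n_g / n_t
        OE += d_g - d_t * p_g
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1)
            V += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    num = float(scores @ OE)
    var = float(scores @ V @ scores)
    if var <= 0:
        return 0.0, 1.0
    chi2 = num**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Optional[Sequence[str]] = None,
    horizon: Optional[float] = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Cox PH fit; returns HR, 95% CI and Wald p per covariate.

    Ties use the Efron approximation (lifelines default). Rank-deficient
    covariate matrices raise; non-convergence is returned as a flagged row.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in df.columns if c not in (duration_col, event_col)
    ]
    data = df[[duration_col, event_col, *covariates]].dropna().copy()
    X = data[covariates].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < len(covariates) + 1:
        raise ValueError("rank-deficient covariate matrix (collinear columns)")
    if horizon is not None:
        t, e = apply_horizon(data[duration_col], data[event_col], horizon)
        data[duration_col] = t
        data[event_col] = e.astype(int)
    if int(data[event_col].sum()) < 1:
        raise ValueError("no events")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            # flagged via the `converged` column instead of warning spam
            warnings.simplefilter("ignore", ConvergenceWarning)
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        logger.warning("Cox fit did not converge: %s", err)
        return pd.DataFrame(
            {
                "covariate": covariates,
                "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "n": len(data),
                "n_events": int(data[event_col].sum()),
                "converged": False,
            }
        )
    summ = cph.summary
    return pd.DataFrame(
        {
            "covariate": summ.index,
            "hr": summ["exp(coef)"].to_numpy(),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
            "n": len(data),
            "n_events": int(data[event_col].sum()),
            "converged": True,
        }
    ).reset_index(drop=True)


def univariable_screen(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    horizon: Optional[float] = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """One Cox fit per covariate; rows concatenated."""
    frames = []
    for cov in covariates:
        try:
            frames.append(cox_fit(df, duration_col, event_col, [cov], horizon))
        except ValueError as err:
            logger.warning("univariable Cox for %s skipped: %s", cov, err)
    return pd.concat(frames, ignore_index=True)


def multivariable_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    entry_p: float = 0.1,
    horizon: Optional[float] = DEFAULT_HORIZON,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariable screen then a single multivariable model.

    Covariates with univariable Wald p < ``entry_p`` enter the multivariable
    model in one step. Returns (univariable table, multivariable table).
    """
    uni = univariable_screen(df, duration_col, event_col, covariates, horizon)
    selected = list(uni.loc[uni["p"] < entry_p, "covariate"])
    if len(selected) < 2:
        return uni, pd.DataFrame(
            columns=["covariate", "hr", "ci_low", "ci_high", "p", "n",
                     "n_events", "converged"]
        )
    multi = cox_fit(df, duration_col, event_col, selected, horizon)
    return uni, multi


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances, Satterthwaite df).

    Returns (t, df, two-sided p). Two zero-variance groups with equal means
    give p = 1 by convention; with unequal means p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def segmentwise_group_test(
    matrix: AtomicSegmentMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-atom Welch t-tests with BH-adjusted q-values.

    Atoms constant in both groups get p = q = 1. The returned table keeps
    atom order and adds a rank column (1 = smallest p).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    A = matrix.estimates[[matrix.sample_index(s) for s in group_a]]
    B = matrix.estimates[[matrix.sample_index(s) for s in group_b]]
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p[degenerate & (ma == mb)] = 1.0
    p[degenerate & (ma != mb)] = 0.0
    t[degenerate] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    out = matrix.atoms[["chrom", "start_bp", "end_bp", "length_bp"]].copy()
    out["mean_a"] = ma
    out["mean_b"] = mb
    out["t"] = t
    out["p"] = p
    out["q"] = q
    out["rank"] = stats.rankdata(p, method="ordinal").astype(int)
    return out


def median_split(scores: dict[str, float]) -> dict[str, str]:
    """Split patients at the cohort median; a score equal to the median is
    assigned to the HIGH group (an odd cohort splits (n-1)/2 low,
    (n+1)/2 high)."""
    values = np.array(list(scores.values()), dtype=float)
    med = float(np.median(values))
    return {pid: ("low" if v < med else "high") for pid, v in scores.items()}


def combined_strata(
    het_scores: dict[str, float],
    complexity_scores: dict[str, float],
    complexity_threshold: float = 25.0,
) -> pd.DataFrame:
    """Three ordered strata from heterogeneity and complexity.

    Stratum 0: heterogeneity below the median AND complexity below the
    threshold; 1: exactly one of the two low; 2: neither. Patients missing
    either score are excluded (logged).
    """
    usable = sorted(set(het_scores) & set(complexity_scores))
    dropped = (set(het_scores) | set(complexity_scores)) - set(usable)
    if dropped:
        logger.info("combined strata: excluded %s (missing a score)", sorted(dropped))
    split = median_split({p: het_scores[p] for p in usable})
    rows = []
    for pid in usable:
        het_low = split[pid] == "low"
        cx_low = complexity_scores[pid] < complexity_threshold
        rows.append((pid, 2 - int(het_low) - int(cx_low)))
    return pd.DataFrame(rows, columns=["patient_id", "stratum"])
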