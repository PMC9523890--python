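"""Subtype validation against clinical data: Wilcoxon rank-sum battery,
elastic-net Cox conversion model, log-rank comparison, conversion and
progression curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "CoxFit",
    "ranksum_battery",
    "fit_cox",
    "concordance_index",
    "logrank_test",
    "conversion_curves",
    "progression_curves",
    "filter_conversion_records",
]


@dataclass
class CoxFit:
    coefficients: pd.Series  # per standardized covariate
    baseline_cumhaz: pd.DataFrame  # Breslow estimate on the event-time grid
    concordance: float
    l1_ratio: float
    strength: float
    covariate_means: pd.Series
    covariate_stds: pd.Series
    dropped_constant: list[str]


def ranksum_battery(
    measures: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) per measure between the
    two label groups, Bonferroni-adjusted at ``alpha / n_measures``.

    The exact null distribution is used when the pooled group size is <= 20
    with no ties; otherwise the tie-corrected normal approximation.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("rank-sum battery expects exactly 2 groups")
    n_measures = measures.shape[1]
    threshold = alpha / n_measures
    rows = []
    for col in measures.columns:
        vals = measures[col]
        ok = vals.notna().to_numpy()
        x = vals[ok & (labels == groups[0])].to_numpy(dtype=float)
        y = vals[ok & (labels == groups[1])].to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            rows.append(
                {"measure": col, "statistic": np.nan, "p_value": np.nan,
                 "neg_log10_p": np.nan, "significant": False, "tested": False}
            )
            continue
        pooled = np.concatenate([x, y])
        exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        p = float(res.pvalue)
        rows.append(
            {
                "measure": col,
                "statistic": float(res.statistic),
                "p_value": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                "significant": bool(p < threshold),
                "tested": True,
            }
        )
    return pd.DataFrame(rows)


def _standardize_covariates(df: pd.DataFrame, covariates: list[str]):
    sub = df[covariates]
    means, stds = sub.mean(), sub.std(ddof=0)
    constant = [c for c in covariates if stds[c] == 0]
    kept = [c for c in covariates if c not in constant]
    Z = (sub[kept] - means[kept]) / stds[kept]
    return Z, means, stds, constant


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    strength: float = 0.1,
    l1_ratio: float = 0.5,
) -> CoxFit:
    """Elastic-net-penalized Cox proportional hazards fit.

    Covariates are z-scored before penalization; constant covariates are
    dropped with coefficient 0 (a penalized fit would shrink them there
    anyway, and they carry no partial-likelihood information). Ties use
    Efron's method, the baseline cumulative hazard is the Breslow estimate
    (both lifelines defaults).
    """
    if records[event_col].sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    Z, means, stds, dropped = _standardize_covariates(records, covariates)
    kept = list(Z.columns)
    coefs = pd.Series(0.0, index=covariates)
    if kept:
        df = pd.concat(
            [records[[duration_col, event_col]].reset_index(drop=True),
             Z.reset_index(drop=True)],
            axis=1,
        )
        cph = CoxPHFitter(penalizer=strength, l1_ratio=l1_ratio)
        cph.fit(df, duration_col=duration_col, event_col=event_col)
        coefs[kept] = cph.params_[kept]
        baseline = cph.baseline_cumulative_hazard_
        risk = (Z.to_numpy() @ coefs[kept].to_numpy()).ravel()
    else:
        grid = np.sort(records.loc[records[event_col] == 1, duration_col].unique())
        # Breslow estimate with no covariates: Nelson-Aalen
        n = len(records)
        cumhaz, H = [], 0.0
        t_all = records[duration_col].to_numpy()
        e_all = records[event_col].to_numpy()
        for t in grid:
            d = int(np.sum((t_all == t) & (e_all == 1)))
            at_risk = int(np.sum(t_all >= t))
            H += d / at_risk
            cumhaz.append(H)
        baseline = pd.DataFrame({"baseline hazard": cumhaz}, index=grid)
        risk = np.zeros(len(records))
    conc = concordance_index(
        risk, records[duration_col].to_numpy(), records[event_col].to_numpy()
    )
    return CoxFit(
        coefficients=coefs,
        baseline_cumhaz=baseline,
        concordance=conc,
        l1_ratio=l1_ratio,
        strength=strength,
        covariate_means=means,
        covariate_stds=stds,
        dropped_constant=dropped,
    )


def concordance_index(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Harrell's C: over pairs where the earlier time is an event, the
    fraction in which the earlier-failing subject has the higher risk score;
    risk ties count 0.5."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    n = len(risk)
    concordant = comparable = 0.0
    for i in range(n):
        if event[i] != 1:
            continue
        later = time > time[i]
        comparable += later.sum()
        concordant += np.sum(risk[later] < risk[i]) + 0.5 * np.sum(
            risk[later] == risk[i]
        )
    if comparable == 0:
        return 0.5
    return float(concordant / comparable)


def logrank_test(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Two-group log-rank test; returns (chi2, p, -log2(p))."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("log-rank comparison needs exactly 2 groups")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    a = groups == uniq[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a],
                      event_observed_B=event[~a])
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    return chi2, p, float(-np.log2(p)) if p > 0 else np.inf


def conversion_curves(
    fit: CoxFit, group_profiles: dict[str, pd.Series]
) -> pd.DataFrame:
    """Survival probability S(t|X) = exp(-H0(t) * exp(beta'X)) on the fit's
    event-time grid, one curve per group covariate profile.

    Profiles are given on the original covariate scale and standardized with
    the fit's training statistics.
    """
    H0 = fit.baseline_cumhaz.iloc[:, 0]
    grid = H0.index.to_numpy(dtype=float)
    rows = []
    kept = [c for c in fit.coefficients.index if c not in fit.dropped_constant]
    for name, profile in group_profiles.items():
        z = np.array(
            [
                (profile[c] - fit.covariate_means[c]) / fit.covariate_stds[c]
                for c in kept
            ]
        )
        lp = float(z @ fit.coefficients[kept].to_numpy()) if kept else 0.0
        surv = np.exp(-H0.to_numpy() * np.exp(lp))
        for t, s in zip(grid, surv):
            rows.append({"group": name, "time_months": t, "survival": s})
    out = pd.DataFrame(rows)
    # prepend t=0 with survival 1 for each group
    zero = pd.DataFrame(
        {"group": list(group_profiles), "time_months": 0.0, "survival": 1.0}
    )
    return (
        pd.concat([zero, out], ignore_index=True)
        .sort_values(["group", "time_months"])
        .reset_index(drop=True)
    )


def progression_curves(
    longitudinal: pd.DataFrame,
    labels: pd.Series,
    horizon: int = 60,
) -> pd.DataFrame:
    """Per-(measure, month, subtype) mean and normal-approximation 95% CI.

    ``longitudinal`` is long-format (sample_id, month, measure, value);
    ``labels`` maps sample_id -> subtype. Months beyond the horizon are
    dropped; cells with fewer than 2 samples are flagged.
    """
    df = longitudinal[longitudinal["month"] <= horizon].copy()
    df["subtype"] = df["sample_id"].map(labels)
    rows = []
    for (measure, month, subtype), grp in df.groupby(
        ["measure", "month", "subtype"], sort=True
    ):
        vals = grp["value"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            half = 1.96 * vals.std(ddof=1) / np.sqrt(n)
        else:
            half = np.nan
        rows.append(
            {
                "measure": measure,
                "month": month,
                "subtype": subtype,
                "n": n,
                "mean": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "underpowered": n < 2,
            }
        )
    return pd.DataFrame(rows)


def filter_conversion_records(
    visits: pd.DataFrame, diagnosis_col: str = "diagnosis"
) -> pd.DataFrame:
    """Keep visit records whose diagnosis is MCI, AD, or MCI-converted-to-AD."""
    keep = visits[diagnosis_col].isin(["MCI", "AD", "MCI_TO_AD"])
    return visits[keep].reset_index(drop=True)
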