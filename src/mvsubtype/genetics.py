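"""Case-control SNP association: per-SNP logistic regression with covariates,
Benjamini-Hochberg FDR control, and a cross-test summary table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "case_control_assoc",
    "bh_fdr",
    "assoc_summary",
    "snp_chromosome",
]

_MAX_ABS_BETA = 15.0  # beyond this the Wald statistic is meaningless (separation)


def _fit_one_snp(y, g, cov):
    """Logistic fit of phenotype on allele count + covariates; returns
    (beta, wald_p) or None when the SNP is untestable."""
    X = np.column_stack([np.ones(len(g)), g] + ([cov] if cov is not None else []))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, warn_convergence=False)
    except Exception:
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    beta = float(res.params[1])
    p = float(res.pvalues[1])
    if not np.isfinite(beta) or not np.isfinite(p) or abs(beta) > _MAX_ABS_BETA:
        return None
    return beta, p


def case_control_assoc(
    genotypes: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    test_name: str = "case_vs_control",
) -> pd.DataFrame:
    """Per-SNP logistic regression of case/control status on additive allele
    count, adjusting for the supplied covariates.

    Missing genotypes are dropped per SNP (complete case). Monomorphic,
    separated or non-converged SNPs are flagged ``testable=False`` rather
    than raising, so a full scan never crashes.
    """
    phenotype = np.asarray(phenotype).astype(float)
    classes = np.unique(phenotype)
    if len(classes) != 2:
        raise ValueError("phenotype must contain both cases and controls")
    y_all = (phenotype == classes.max()).astype(float)

    snp_cols = [c for c in genotypes.columns if c != "sample_id"]
    cov_all = None
    if covariates is not None:
        cov_cols = [c for c in covariates.columns if c != "sample_id"]
        cov_all = covariates[cov_cols].to_numpy(dtype=float)

    rows = []
    for snp in snp_cols:
        g = genotypes[snp].to_numpy(dtype=float)
        ok = np.isfinite(g)
        g_ok, y_ok = g[ok], y_all[ok]
        cov_ok = cov_all[ok] if cov_all is not None else None
        result = None
        if len(np.unique(g_ok)) >= 2 and len(np.unique(y_ok)) == 2:
            result = _fit_one_snp(y_ok, g_ok, cov_ok)
        if result is None:
            rows.append(
                {"snp_id": snp, "test": test_name, "beta": np.nan,
                 "p_value": np.nan, "neg_log10_p": np.nan, "testable": False}
            )
        else:
            beta, p = result
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            rows.append(
                {"snp_id": snp, "test": test_name, "beta": beta, "p_value": p,
                 "neg_log10_p": float(-np.log10(p)), "testable": True}
            )
    out = pd.DataFrame(rows)
    out["significant"] = bh_fdr(out["p_value"].to_numpy(), q=0.05)
    return out


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags.

    NaN entries (untestable SNPs) are excluded from the testing family and
    reported as not rejected.
    """
    p = np.asarray(p_values, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    tested = np.isfinite(p)
    m = int(tested.sum())
    if m == 0:
        return reject
    pt = p[tested]
    order = np.argsort(pt, kind="stable")
    sorted_p = pt[order]
    thresholds = q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresholds)[0]
    if below.size:
        k = below[-1]
        flags = np.zeros(m, dtype=bool)
        flags[order[: k + 1]] = True
        reject[tested] = flags
    return reject


def snp_chromosome(snp_id: str) -> int:
    """Parse the chromosome number from ids like ``chr7_snp00042``; SNPs
    without the prefix sort last."""
    if snp_id.startswith("chr"):
        head = snp_id[3:].split("_", 1)[0]
        if head.isdigit():
            return int(head)
    return 10**6


def assoc_summary(
    results: list[pd.DataFrame], q: float = 0.05, joint: bool = False
) -> pd.DataFrame:
    """Wide -log10(p) table restricted to SNPs significant in >= 1 test,
    ordered by chromosome.

    BH is applied per-test by default (``joint=True`` pools all tests into
    one family). Non-significant cells keep their p-value.
    """
    frames = []
    for df in results:
        df = df.copy()
        frames.append(df)
    if joint:
        pooled = pd.concat(frames, ignore_index=True)
        pooled["significant"] = bh_fdr(pooled["p_value"].to_numpy(), q)
        frames = [g.copy() for _, g in pooled.groupby("test", sort=False)]
    else:
        for df in frames:
            df["significant"] = bh_fdr(df["p_value"].to_numpy(), q)
    combined = pd.concat(frames, ignore_index=True)
    keep_snps = combined.loc[combined["significant"], "snp_id"].unique()
    if len(keep_snps) == 0:
        return pd.DataFrame()
    sub = combined[combined["snp_id"].isin(keep_snps)]
    wide = sub.pivot_table(
        index="snp_id", columns="test", values="neg_log10_p", aggfunc="first"
    )
    wide = wide.loc[
        sorted(wide.index, key=lambda s: (snp_chromosome(s), s))
    ]
    return wide
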