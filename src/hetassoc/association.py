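"""Case-control association and descriptive statistics.

The core model is a logistic regression of disease status on a z-scored
heterozygosity metric, optionally adjusted for age, sex, BMI and diabetes.
The exponentiated coefficient is the odds ratio per standard deviation of
the metric; OR < 1 means higher heterozygosity is protective.  The full
analysis grid crosses 2 MAF strata × 2 metrics × 3 case subgroups (all,
hip-only, knee-only — each subgroup keeps the full control set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import ASSOCIATION_COLUMNS, SampleTable

logger = logging.getLogger(__name__)

METRICS = ("het_rate", "het_excess")
SUBGROUPS = ("all_oa", "hip", "knee")

#: sample-table covariate encodings used in the design matrix
_COVARIATE_CODERS = {
    "age": lambda df: df["age"].astype(float),
    "sex": lambda df: df["sex"].map({"female": 0.0, "male": 1.0}),
    "bmi": lambda df: df["bmi"].astype(float),
    "diabetes": lambda df: df["diabetes"].map({"no": 0.0, "yes": 1.0}),
}


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


@dataclass
class AssociationResult:
    stratum: str
    metric: str
    subgroup: str
    n_case: int
    n_control: int
    beta: float
    se: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    covariates: list[str] = field(default_factory=list)
    converged: bool = True

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        d["covariates"] = "+".join(self.covariates) if self.covariates else "none"
        d.pop("converged")
        return d


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_rtol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS (Newton scoring).

    ``X`` must include the intercept column.  Convergence is declared when
    the largest score component falls below ``score_tol`` or the relative
    log-likelihood change falls below ``ll_rtol``.  Complete separation
    (monotone likelihood, diverging coefficients) is detected and reported
    as ``converged=False`` with the last iterate; Wald standard errors come
    from the observed information at the final estimate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
        raise ValueError("outcome must contain both classes coded 0/1")

    beta = np.zeros(X.shape[1])
    ll_old = _loglik(y, X @ beta)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # dampen absurd Newton steps (near-separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        ll = _loglik(y, X @ beta)
        if np.max(np.abs(beta)) > 30.0:
            separated = True
            break
        if abs(ll - ll_old) < ll_rtol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll

    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    if separated:
        logger.warning("fit_logistic: complete separation detected")
        converged = False
    return LogisticFit(beta=beta, se=se, loglik=_loglik(y, eta),
                       converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# association of heterozygosity with case status
# ---------------------------------------------------------------------------

def _subgroup_frame(
    profiles: pd.DataFrame, samples: SampleTable, subgroup: str
) -> pd.DataFrame:
    merged = profiles.merge(samples.df, on="sample_id", how="inner")
    if subgroup == "all_oa":
        return merged
    if subgroup not in ("hip", "knee"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    keep = (merged["status"] == "control") | (merged["joint"] == subgroup)
    return merged.loc[keep]


def association_test(
    profiles: pd.DataFrame,
    samples: SampleTable,
    metric: str = "het_excess",
    subgroup: str = "all_oa",
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Logistic regression of case status on one z-scored heterozygosity
    metric within one subgroup.

    ``profiles`` must hold a single MAF stratum.  Rows with a missing
    covariate are dropped listwise (count logged).  Returns the per-SD odds
    ratio with a 95% Wald CI.
    """
    covariates = list(covariates or [])
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    strata = profiles["stratum"].unique()
    if len(strata) != 1:
        raise ValueError("profiles must contain exactly one stratum")
    unknown = [c for c in covariates if c not in _COVARIATE_CODERS]
    if unknown:
        raise ValueError(f"unknown covariate(s): {unknown}")

    df = _subgroup_frame(profiles, samples, subgroup)
    if df.empty:
        raise ValueError(f"empty subgroup {subgroup!r}")
    cols = {"z": df[f"z_{metric}"].astype(float)}
    for c in covariates:
        cols[c] = _COVARIATE_CODERS[c](df)
    design = pd.DataFrame(cols, index=df.index)
    complete = design.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("association_test: %d row(s) dropped for missing covariates",
                    n_dropped)
    df = df.loc[complete]
    design = design.loc[complete]
    y = (df["status"] == "case").to_numpy(float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class after filtering")

    X = np.column_stack([np.ones(len(df)), design.to_numpy(float)])
    fit = fit_logistic(y, X)
    beta, se = float(fit.beta[1]), float(fit.se[1])
    z = beta / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return AssociationResult(
        stratum=str(strata[0]),
        metric=metric,
        subgroup=subgroup,
        n_case=int(y.sum()),
        n_control=int((1 - y).sum()),
        beta=beta,
        se=se,
        or_per_sd=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=max(p, np.finfo(float).tiny),
        covariates=covariates,
        converged=fit.converged,
    )


def analysis_grid(
    profiles: pd.DataFrame,
    samples: SampleTable,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """The full 2 strata × 2 metrics × 3 subgroups association grid.

    ``profiles`` holds both MAF strata (output of
    :func:`~hetassoc.heterozygosity.compute_strata`).  Rows come back in
    deterministic (stratum, metric, subgroup) order.
    """
    rows = []
    for stratum in sorted(profiles["stratum"].unique()):
        sub = profiles.loc[profiles["stratum"] == stratum]
        for metric in METRICS:
            for subgroup in SUBGROUPS:
                res = association_test(sub, samples, metric, subgroup, covariates)
                rows.append(res.to_row())
    return pd.DataFrame(rows)[ASSOCIATION_COLUMNS]


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p (t transform, n−2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def students_ttest(x, y) -> tuple[float, float]:
    """Two-sided two-sample Student t-test (pooled variance)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Chi-square test (no continuity correction) comparing two proportions."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        import warnings

        warnings.warn("proportion_test: expected cell count < 1; p unreliable")
    if table.sum(axis=0).min() == 0:
        return 1.0  # degenerate margin: no information
    chi2 = float((((table - expected) ** 2) / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def cohort_summary(samples: SampleTable) -> pd.DataFrame:
    """Cohort descriptives in the usual case/control table shape.

    One row per group (case, hip, knee, control): n, mean ± SD age and BMI,
    % female; plus case-vs-control and hip-vs-knee p-values (t-test for age
    and BMI, chi-square for sex).
    """
    df = samples.df
    groups = {
        "case": df[df.status == "case"],
        "hip": df[df.joint == "hip"],
        "knee": df[df.joint == "knee"],
        "control": df[df.status == "control"],
    }
    if groups["case"].empty or groups["control"].empty:
        raise ValueError("need both cases and controls")
    rows = []
    for name, gdf in groups.items():
        age = gdf["age"].dropna().astype(float)
        bmi = gdf["bmi"].dropna().astype(float)
        sex = gdf["sex"].dropna()
        rows.append(
            {
                "group": name,
                "n": len(gdf),
                "mean_age": age.mean() if len(age) else np.nan,
                "sd_age": age.std(ddof=1) if len(age) > 1 else np.nan,
                "pct_female": 100.0 * (sex == "female").mean() if len(sex) else np.nan,
                "mean_bmi": bmi.mean() if len(bmi) else np.nan,
                "sd_bmi": bmi.std(ddof=1) if len(bmi) > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows)

    def _pvals(a: pd.DataFrame, b: pd.DataFrame) -> dict:
        res = {}
        for col in ("age", "bmi"):
            xa = a[col].dropna().astype(float)
            xb = b[col].dropna().astype(float)
            try:
                res[f"p_{col}"] = students_ttest(xa, xb)[1]
            except ValueError:
                res[f"p_{col}"] = np.nan
        sa, sb = a["sex"].dropna(), b["sex"].dropna()
        if len(sa) and len(sb):
            res["p_sex"] = proportion_test(
                int((sa == "female").sum()), len(sa),
                int((sb == "female").sum()), len(sb),
            )
        else:
            res["p_sex"] = np.nan
        return res

    comparisons = {
        "case_vs_control": _pvals(groups["case"], groups["control"]),
        "hip_vs_knee": (
            _pvals(groups["hip"], groups["knee"])
            if len(groups["hip"]) and len(groups["knee"])
            else {"p_age": np.nan, "p_bmi": np.nan, "p_sex": np.nan}
        ),
    }
    for name, pv in comparisons.items():
        for k, v in pv.items():
            out.loc[out["group"] == ("case" if "case" in name else "hip"), k] = v
    return out
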