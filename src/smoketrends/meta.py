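"""Two-stage individual-participant-data meta-analysis and meta-regression.

Stage 1 fits, within each study, a logistic regression of current smoking
on education (three levels, high = reference) adjusted for 10-year age
bands, yielding a log odds ratio and its variance per study.  Stage 2
pools the study effects with inverse-variance weights under a
random-effects model whose between-study variance tau^2 is estimated by
the DerSimonian-Laird moment estimator; heterogeneity is summarised by
Cochran's Q and I^2 (between-study variance as a share of total variance).
Trends in study-level estimates over calendar time are assessed by
random-effects meta-regression with tau^2 estimated by REML (iterative
Fisher scoring; a method-of-moments estimator is available as a
cross-check).

The pooling and meta-regression arithmetic is implemented here directly —
the DL, Q, I^2 and REML formulas are the point — while the stage-1
logistic fits use the GLM machinery of statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError, DataError, NumericalError, StudyExclusionError

EDU_REFERENCE = "high"


@dataclass(frozen=True)
class StudyEffect:
    """One study's log odds ratio (a given education level vs high)."""

    study: str
    effect: float
    variance: float
    covariate: float = np.nan  # e.g. central calendar year

    def __post_init__(self):
        if not self.variance > 0:
            raise ConfigurationError(f"effect variance must be positive, got {self.variance}")


@dataclass(frozen=True)
class PooledEffect:
    effect: float
    se: float
    ci_low: float
    ci_high: float
    q: float
    tau2: float
    i2: float       # fraction in [0,1); NaN when undefined (k = 1)
    k: int
    weights: np.ndarray  # normalized random-effects weights
    studies: tuple = ()

    @property
    def p_value(self) -> float:
        return float(2 * stats.norm.sf(abs(self.effect / self.se)))


@dataclass(frozen=True)
class MetaRegressionFit:
    intercept: float
    slope: float
    slope_se: float
    p_value: float
    tau2: float
    k: int
    method: str
    n_iter: int = 0


# ---------------------------------------------------------------------------
# stage 1


def _age_band(ages, width: int = 10):
    lo = (np.asarray(ages) // width) * width
    return lo.astype(int).astype(str)


def first_stage_fit(records: pd.DataFrame, contrast: str = "low",
                    outcome: str = "current_smoker",
                    age_band_width: int = 10) -> StudyEffect:
    """Within-study age-adjusted log OR of smoking for ``contrast``
    education ('low' or 'secondary') versus high.

    Records are aggregated to education x age-band binomial cells before
    fitting (identical maximum-likelihood estimate, much faster).  Studies
    where a contrast category is absent, has no respondents with both
    outcomes, or separates perfectly are rejected with
    :class:`StudyExclusionError` carrying the reason.
    """
    if contrast not in ("low", "secondary"):
        raise ConfigurationError(f"contrast must be 'low' or 'secondary', got {contrast!r}")
    if outcome not in records.columns:
        raise DataError(f"outcome column {outcome!r} missing")
    study = str(records["survey"].iloc[0]) if "survey" in records.columns else "study"

    df = records[[outcome, "education", "age"]].copy()
    df["band"] = _age_band(df["age"], age_band_width)
    cells = (df.groupby(["education", "band"], observed=True)[outcome]
               .agg(smokers="sum", n="size").reset_index())

    for level in (contrast, EDU_REFERENCE):
        sub = cells[cells["education"] == level]
        if sub.empty:
            raise StudyExclusionError(study, f"education level {level!r} absent")
        s, n = int(sub["smokers"].sum()), int(sub["n"].sum())
        if s == 0 or s == n:
            raise StudyExclusionError(
                study, f"education level {level!r} has a single outcome (separation)")

    levels = [lv for lv in ("low", "secondary") if (cells["education"] == lv).any()]
    bands = sorted(cells["band"].unique())
    X = pd.DataFrame({"const": 1.0}, index=cells.index)
    for lv in levels:
        X[f"edu_{lv}"] = (cells["education"] == lv).astype(float)
    for b in bands[1:]:
        X[f"band_{b}"] = (cells["band"] == b).astype(float)

    endog = np.column_stack([cells["smokers"], cells["n"] - cells["smokers"]])
    try:
        with warnings.catch_warnings():
            # saturated-cell and separation warnings are handled by the
            # explicit diagnostics below
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # statsmodels raises various convergence errors
        raise StudyExclusionError(study, f"logistic fit failed: {exc}") from exc
    name = f"edu_{contrast}"
    beta = float(fit.params[name])
    var = float(fit.cov_params().loc[name, name])
    if not np.isfinite(beta) or not np.isfinite(var) or abs(beta) > 15:
        raise StudyExclusionError(study, "non-finite or diverging estimate (separation)")
    year = float(records["year"].mean()) if "year" in records.columns else np.nan
    return StudyEffect(study=study, effect=beta, variance=var, covariate=year)


def fit_all_studies(records: pd.DataFrame, contrast: str = "low",
                    outcome: str = "current_smoker"):
    """First-stage fits for every study in a combined record set; returns
    (effects, exclusions) where exclusions maps study -> reason."""
    effects, excluded = [], {}
    for study, sub in records.groupby("survey", observed=True):
        try:
            effects.append(first_stage_fit(sub, contrast=contrast, outcome=outcome))
        except StudyExclusionError as e:
            excluded[str(study)] = e.reason
    return effects, excluded


# ---------------------------------------------------------------------------
# stage 2


def dl_pool(effects) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling.

    Fixed-effect weights w_i = 1/v_i give Cochran's
    Q = sum w_i (theta_i - theta_bar)^2;
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w));
    random-effects weights 1/(v_i + tau^2); I^2 = max(0, (Q - (k-1)) / Q).
    With a single study the effect passes through, tau^2 = 0 and I^2 is
    reported as missing (NaN).
    """
    effects = list(effects)
    k = len(effects)
    if k == 0:
        raise DataError("nothing to pool")
    th = np.array([e.effect for e in effects])
    v = np.array([e.variance for e in effects])
    studies = tuple(e.study for e in effects)
    if k == 1:
        se = float(np.sqrt(v[0]))
        z = stats.norm.ppf(0.975)
        return PooledEffect(effect=float(th[0]), se=se,
                            ci_low=float(th[0] - z * se), ci_high=float(th[0] + z * se),
                            q=0.0, tau2=0.0, i2=np.nan, k=1,
                            weights=np.array([1.0]), studies=studies)
    w = 1.0 / v
    theta_fe = float(w @ th / w.sum())
    q = float(w @ (th - theta_fe) ** 2)
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    wr = 1.0 / (v + tau2)
    pooled = float(wr @ th / wr.sum())
    se = float(np.sqrt(1.0 / wr.sum()))
    z = stats.norm.ppf(0.975)
    return PooledEffect(effect=pooled, se=se,
                        ci_low=pooled - z * se, ci_high=pooled + z * se,
                        q=q, tau2=float(tau2), i2=float(i2), k=k,
                        weights=wr / wr.sum(), studies=studies)


def _reml_tau2(y, v, X, tol: float = 1e-8, maxiter: int = 200):
    """REML estimate of the residual between-study variance by Fisher
    scoring on the REML score of tau^2."""
    k, p = X.shape
    tau2 = max(0.0, float(np.var(y, ddof=1) - np.mean(v)))
    log = []
    for it in range(1, maxiter + 1):
        W = 1.0 / (v + tau2)
        XtWX = X.T @ (X * W[:, None])
        try:
            M = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular design in REML iteration {it}") from exc
        P = np.diag(W) - (X * W[:, None]) @ M @ (X * W[:, None]).T
        Py = P @ y
        score = -0.5 * np.trace(P) + 0.5 * float(y @ P @ Py)
        info = 0.5 * np.trace(P @ P)
        step = score / info
        new = max(0.0, tau2 + step)
        log.append((it, tau2, score))
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new, it
        tau2 = new
    raise NumericalError(
        f"REML did not converge in {maxiter} iterations; trace tail: {log[-3:]}")


def _mm_tau2(y, v, X):
    """Method-of-moments residual tau^2 (DL-type, regression analogue)."""
    k, p = X.shape
    w = 1.0 / v
    XtWX = X.T @ (X * w[:, None])
    M = np.linalg.inv(XtWX)
    H = X @ M @ (X * w[:, None]).T
    resid = y - H @ y
    qe = float(w @ resid ** 2)
    trP = w.sum() - np.trace(M @ (X.T @ (X * (w ** 2)[:, None])))
    return max(0.0, (qe - (k - p)) / trP)


def meta_regress(effects, tau2_method: str = "reml",
                 tol: float = 1e-8, maxiter: int = 200) -> MetaRegressionFit:
    """Random-effects meta-regression of study effects on their covariate
    (calendar year): weighted least squares with weights 1/(v_i + tau^2),
    slope tested by normal approximation."""
    effects = list(effects)
    k = len(effects)
    if k < 3:
        raise ConfigurationError(f"meta-regression needs at least 3 studies, got {k}")
    y = np.array([e.effect for e in effects])
    v = np.array([e.variance for e in effects])
    x = np.array([e.covariate for e in effects], dtype=float)
    if np.any(~np.isfinite(x)):
        raise ConfigurationError("every effect needs a finite covariate")
    if np.var(x) == 0:
        raise ConfigurationError("covariate is constant across studies")
    X = np.column_stack([np.ones(k), x])
    if tau2_method == "reml":
        tau2, n_iter = _reml_tau2(y, v, X, tol=tol, maxiter=maxiter)
    elif tau2_method == "mm":
        tau2, n_iter = _mm_tau2(y, v, X), 0
    else:
        raise ConfigurationError(f"unknown tau2 method {tau2_method!r}")
    W = 1.0 / (v + tau2)
    XtWX = X.T @ (X * W[:, None])
    M = np.linalg.inv(XtWX)
    beta = M @ (X.T @ (W * y))
    slope_se = float(np.sqrt(M[1, 1]))
    pval = float(2 * stats.norm.sf(abs(beta[1] / slope_se)))
    return MetaRegressionFit(intercept=float(beta[0]), slope=float(beta[1]),
                             slope_se=slope_se, p_value=pval, tau2=float(tau2),
                             k=k, method=tau2_method, n_iter=n_iter)


def forest_table(effects, pooled: PooledEffect) -> pd.DataFrame:
    """Forest-plot data: per-study OR with 95% CI and weight (%), plus a
    pooled row carrying Q, tau^2, I^2 and the pooled p-value."""
    effects = list(effects)
    z = stats.norm.ppf(0.975)
    rows = []
    for e, w in zip(effects, pooled.weights):
        se = np.sqrt(e.variance)
        rows.append({"study": e.study, "or": float(np.exp(e.effect)),
                     "ci_low": float(np.exp(e.effect - z * se)),
                     "ci_high": float(np.exp(e.effect + z * se)),
                     "weight_pct": 100.0 * float(w),
                     "q": np.nan, "tau2": np.nan, "i2_pct": np.nan,
                     "p_value": np.nan})
    rows.append({"study": "pooled", "or": float(np.exp(pooled.effect)),
                 "ci_low": float(np.exp(pooled.ci_low)),
                 "ci_high": float(np.exp(pooled.ci_high)),
                 "weight_pct": 100.0,
                 "q": pooled.q, "tau2": pooled.tau2,
                 "i2_pct": 100.0 * pooled.i2 if np.isfinite(pooled.i2) else np.nan,
                 "p_value": pooled.p_value})
    return pd.DataFrame(rows)
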