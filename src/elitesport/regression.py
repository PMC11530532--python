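"""Group-level regression models of expertise on the eight domain scores.

Four logistic models predict elite status (elite = 1, semi-elite = 0) from
the eight standardized domain scores, optionally controlling for sex
(female = 1) and/or age; four linear models predict the continuous 2-16
expertise value from the same designs. Logistic fits report per-term B,
SE, Wald = (B/SE)^2, p, odds-ratio 95% CIs, the likelihood-ratio model
chi-square, Nagelkerke's pseudo R-squared, and the fraction correctly
classified at a 0.5 probability cut. Linear fits report coefficients with
a heteroscedasticity-aware standard-error policy: ordinary SEs unless the
Breusch-Pagan test rejects homoscedasticity (then HC3), escalating to HC4
when the residuals additionally fail a Shapiro-Wilk normality test.

A separate diagnostic battery computes the Durbin-Watson statistic,
Breusch-Pagan test, per-term VIFs, per-case Cook's distance, leverage, and
Studentized residuals (report-only flags), plus a Box-Tidwell linearity
check for the logistic models.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import (
    OLSInfluence,
    variance_inflation_factor,
)
from statsmodels.stats.stattools import durbin_watson

from .errors import SeparationError, ValidationError
from .schemes import DOMAINS
from .scoring import ScoreTable

#: |B| beyond which a logistic coefficient is treated as evidence of
#: (quasi-)complete separation on standardized predictors.
_SEPARATION_B = 15.0


def _design(
    frame: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Listwise-complete design matrix (with intercept) and outcomes."""
    bad = set(covariates) - {"age", "sex"}
    if bad:
        raise ValidationError(f"unsupported covariate(s): {sorted(bad)}")
    cols = list(DOMAINS)
    x = frame[cols].copy()
    if "age" in covariates:
        x["age"] = frame["age"].astype(float)
    if "sex" in covariates:
        x["female"] = (frame["sex"] == "female").astype(float)
    keep = x.notna().all(axis=1)
    x = x[keep]
    used = frame[keep]
    constant = [c for c in x.columns if x[c].nunique() <= 1]
    if constant:
        raise ValidationError(
            f"constant predictor column(s) {constant}: standard errors undefined"
        )
    x = sm.add_constant(x, prepend=True)
    return x, used, frame[keep]


def _separating_term(x: pd.DataFrame, y: pd.Series) -> str:
    """Best candidate for a (quasi-)separating predictor.

    A term whose class-conditional supports do not overlap separates
    completely; otherwise the term most correlated with the outcome is
    reported.
    """
    best, best_corr = None, -1.0
    for col in x.columns:
        if col == "const":
            continue
        ones, zeros = x.loc[y == 1, col], x.loc[y == 0, col]
        if ones.min() > zeros.max() or ones.max() < zeros.min():
            return col
        corr = abs(np.corrcoef(x[col], y)[0, 1])
        if corr > best_corr:
            best, best_corr = col, corr
    return best


@dataclass
class LogisticFit:
    """Results of one binomial logistic regression of elite status."""

    terms: pd.DataFrame          # term, B, SE, wald, p, OR, or_ci_low, or_ci_high
    chi2: float                  # likelihood-ratio model chi-square
    df_model: int
    p_model: float
    nagelkerke_r2: float
    pct_correct: float           # % classified correctly at probability 0.5
    n: int
    llf: float
    llnull: float
    covariates: tuple[str, ...]
    result: object = field(repr=False, default=None)

    def __post_init__(self):
        terms = self.terms
        assert np.allclose(terms["wald"], (terms["B"] / terms["SE"]) ** 2)


@dataclass
class LinearFit:
    """Results of one multiple linear regression of the expertise value."""

    terms: pd.DataFrame          # term, beta, SE, t, p
    r2: float
    adj_r2: float
    f_stat: float
    f_df: tuple[int, int]
    f_p: float
    se_type: str                 # OLS | HC3 | HC4
    bp_stat: float
    bp_df: int
    bp_p: float
    shapiro_p: float
    n: int
    covariates: tuple[str, ...]
    result: object = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo R-squared."""
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    return float(cox_snell / max_cs)


def fit_logistic(
    table: ScoreTable | pd.DataFrame, covariates: tuple[str, ...] = ()
) -> LogisticFit:
    """Maximum-likelihood logistic regression of elite status.

    ``covariates`` may include 'age' and/or 'sex'; rows with any missing
    predictor are dropped listwise. Rejects single-class outcomes and
    detected complete separation (naming the separating term).
    """
    frame = table.frame if isinstance(table, ScoreTable) else table
    x, used, _ = _design(frame, tuple(covariates))
    y = used["elite"].astype(float)
    if y.nunique() < 2:
        raise ValidationError(
            "both elite and semi-elite athletes are required for the "
            f"logistic model; got a single class (n={len(y)})"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # singular Hessian / perfect separation
        term = _separating_term(x, y)
        raise SeparationError(
            term,
            f"logistic fit failed ({exc}); complete separation detected on "
            f"term {term!r}",
        ) from exc
    params = result.params
    if (params.drop("const").abs() > _SEPARATION_B).any():
        term = params.drop("const").abs().idxmax()
        raise SeparationError(
            term,
            f"complete separation suspected: |B| for {term!r} is "
            f"{params[term]:.1f} on a standardized predictor",
        )
    se = result.bse
    wald = (params / se) ** 2
    terms = pd.DataFrame({
        "term": params.index,
        "B": params.to_numpy(),
        "SE": se.to_numpy(),
        "wald": wald.to_numpy(),
        "p": stats.chi2.sf(wald.to_numpy(), 1),
        "OR": np.exp(params.to_numpy()),
        "or_ci_low": np.exp(params.to_numpy() - 1.96 * se.to_numpy()),
        "or_ci_high": np.exp(params.to_numpy() + 1.96 * se.to_numpy()),
    }).reset_index(drop=True)
    chi2 = 2.0 * (result.llf - result.llnull)
    df_model = x.shape[1] - 1
    predicted = (result.predict(x) >= 0.5).astype(float)
    return LogisticFit(
        terms=terms,
        chi2=float(chi2),
        df_model=df_model,
        p_model=float(stats.chi2.sf(chi2, df_model)),
        nagelkerke_r2=nagelkerke_r2(result.llf, result.llnull, len(y)),
        pct_correct=float((predicted == y).mean() * 100.0),
        n=len(y),
        llf=float(result.llf),
        llnull=float(result.llnull),
        covariates=tuple(covariates),
        result=result,
    )


def hc4_covariance(x: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """HC4 heteroscedasticity-consistent covariance (Cribari-Neto).

    V = (X'X)^-1 X' diag(e_i^2 / (1 - h_ii)^d_i) X (X'X)^-1 with
    d_i = min(4, n * h_ii / p).
    """
    x = np.asarray(x, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    h = np.einsum("ij,jk,ik->i", x, xtx_inv, x)
    delta = np.minimum(4.0, n * h / p)
    omega = e ** 2 / (1.0 - h) ** delta
    return xtx_inv @ (x.T * omega) @ x @ xtx_inv


def fit_linear(
    table: ScoreTable | pd.DataFrame,
    covariates: tuple[str, ...] = (),
    se_policy: str = "auto",
) -> LinearFit:
    """OLS regression of the expertise value with an HC-aware SE policy.

    ``se_policy`` is 'auto' (Breusch-Pagan p < .05 selects HC3; a
    Shapiro-Wilk residual-normality rejection additionally escalates to
    HC4), or one of 'OLS', 'HC3', 'HC4' to force an estimator.
    """
    frame = table.frame if isinstance(table, ScoreTable) else table
    x, used, _ = _design(frame, tuple(covariates))
    y = used["expertise"].astype(float)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        corr = x.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        a, b = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {x.shape[1]}); most "
            f"collinear terms: {corr.index[a]!r} and {corr.columns[b]!r}"
        )
    result = sm.OLS(y, x).fit()
    resid = result.resid.to_numpy()
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, x.to_numpy())
    shapiro_p = float(stats.shapiro(resid).pvalue)

    if se_policy == "auto":
        if bp_p < 0.05:
            se_type = "HC4" if shapiro_p < 0.05 else "HC3"
        else:
            se_type = "OLS"
    elif se_policy in ("OLS", "HC3", "HC4"):
        se_type = se_policy
    else:
        raise ValidationError(f"unknown se_policy {se_policy!r}")

    if se_type == "OLS":
        se = result.bse.to_numpy()
    elif se_type == "HC3":
        se = result.HC3_se.to_numpy()
    else:
        se = np.sqrt(np.diag(hc4_covariance(x.to_numpy(), resid)))

    beta = result.params.to_numpy()
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), result.df_resid)
    terms = pd.DataFrame({
        "term": result.params.index, "beta": beta, "SE": se, "t": t, "p": p,
    }).reset_index(drop=True)
    return LinearFit(
        terms=terms,
        r2=float(result.rsquared),
        adj_r2=float(result.rsquared_adj),
        f_stat=float(result.fvalue),
        f_df=(int(result.df_model), int(result.df_resid)),
        f_p=float(result.f_pvalue),
        se_type=se_type,
        bp_stat=float(bp_stat),
        bp_df=x.shape[1] - 1,
        bp_p=float(bp_p),
        shapiro_p=shapiro_p,
        n=len(y),
        covariates=tuple(covariates),
        result=result,
        design=x,
    )


@dataclass
class DiagnosticReport:
    """Regression diagnostics with report-only outlier flags."""

    durbin_watson: float
    dw_in_range: bool                 # inside the conventional [1.5, 2.5]
    bp_stat: float
    bp_df: int
    bp_p: float
    vif: pd.Series                    # per non-constant term
    vif_flagged: list                 # VIF > 10
    cases: pd.DataFrame               # cooks_d, leverage, studentized
    outlier_flags: pd.DataFrame       # boolean flags per case
    available: bool = True
    note: str = ""


def diagnose_linear(fit: LinearFit) -> DiagnosticReport:
    """Durbin-Watson, Breusch-Pagan, VIFs, and per-case influence flags.

    Flags: |Studentized residual| > 3, leverage > 0.2, Cook's D >= 1.
    All flags are report-only; no cases are excluded.
    """
    x = fit.design
    result = fit.result
    n, p = x.shape
    if n < p + 2:
        return DiagnosticReport(
            durbin_watson=float("nan"), dw_in_range=False,
            bp_stat=float("nan"), bp_df=p - 1, bp_p=float("nan"),
            vif=pd.Series(dtype=float), vif_flagged=[],
            cases=pd.DataFrame(), outlier_flags=pd.DataFrame(),
            available=False,
            note=f"diagnostics unavailable: n={n} < p+2={p + 2}",
        )
    resid = result.resid.to_numpy()
    dw = float(durbin_watson(resid))
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, x.to_numpy())
    exog = x.to_numpy()
    names = [c for c in x.columns if c != "const"]
    vif = pd.Series(
        [variance_inflation_factor(exog, x.columns.get_loc(c)) for c in names],
        index=names,
    )
    influence = OLSInfluence(result)
    cases = pd.DataFrame({
        "cooks_d": influence.cooks_distance[0],
        "leverage": influence.hat_matrix_diag,
        "studentized": influence.resid_studentized_external,
    }, index=x.index)
    flags = pd.DataFrame({
        "studentized_gt3": cases["studentized"].abs() > 3.0,
        "leverage_gt_0.2": cases["leverage"] > 0.2,
        "cooks_ge_1": cases["cooks_d"] >= 1.0,
    }, index=x.index)
    return DiagnosticReport(
        durbin_watson=dw,
        dw_in_range=1.5 <= dw <= 2.5,
        bp_stat=float(bp_stat),
        bp_df=p - 1,
        bp_p=float(bp_p),
        vif=vif,
        vif_flagged=[c for c in names if vif[c] > 10.0],
        cases=cases,
        outlier_flags=flags,
    )


def box_tidwell(
    table: ScoreTable | pd.DataFrame, covariates: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Box-Tidwell linearity check for the logistic model.

    Each predictor x is shifted by (1 - min(x)) to be strictly positive
    and an x * ln(x) term is added; a significant augmented term indicates
    a nonlinear logit relationship. Returns the augmented-term table.
    """
    frame = table.frame if isinstance(table, ScoreTable) else table
    x, used, _ = _design(frame, tuple(covariates))
    y = used["elite"].astype(float)
    aug = x.copy()
    for col in x.columns:
        if col == "const":
            continue
        shifted = x[col] + (1.0 - x[col].min())
        aug[f"{col}_xlnx"] = shifted * np.log(shifted)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.Logit(y, aug).fit(disp=0, maxiter=200)
    rows = []
    for col in aug.columns:
        if not col.endswith("_xlnx"):
            continue
        b, se = result.params[col], result.bse[col]
        wald = (b / se) ** 2
        rows.append({
            "term": col[: -len("_xlnx")], "B_xlnx": b, "SE": se,
            "wald": wald, "p": stats.chi2.sf(wald, 1),
        })
    return pd.DataFrame(rows)


def fit_all_models(table: ScoreTable, se_policy: str = "auto") -> dict:
    """The four logistic and four linear models (a)-(d)."""
    specs = {"a": (), "b": ("sex",), "c": ("age",), "d": ("sex", "age")}
    return {
        "logistic": {k: fit_logistic(table, cov) for k, cov in specs.items()},
        "linear": {
            k: fit_linear(table, cov, se_policy=se_policy)
            for k, cov in specs.items()
        },
    }
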