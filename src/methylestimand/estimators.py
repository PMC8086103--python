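"""Per-CpG estimators for the four ways of reporting a methylation effect.

Each fitter returns one row per CpG with the model intercept, the treatment
coefficient, confounder coefficients where adjusted, a p-value for the
treatment coefficient, a convergence flag and the derived *estimand* — the
quantity a reader should report:

``gaussian_beta``           OLS on Beta-values; estimand is the coefficient
                            itself, a difference in Beta-values.
``beta_regression``         Beta-distribution regression (logit mean link);
                            estimand is exp(coef), a methylation-odds ratio.
``raw_beta_diff``           Difference of group Beta means; the p-value
                            comes from a companion unadjusted M-scale fit.
``m_regression_intercept``  OLS on M-values with covariates; estimand is
                            the intercept-method ΔBeta, the
                            confounder-adjusted difference in Beta-values.

Mass OLS fitting is vectorised across CpGs (one linear solve for the whole
matrix, limma-style); beta regression is fitted per CpG by Newton-Raphson
maximum likelihood and failures are recorded, never silently dropped.

Covariate coding: the treatment indicator is 0/1 with Placebo as reference;
age is centred at the placebo-group sample mean and scaled by the pooled
SD; sex (0/1) is centred at the placebo-group sample proportion.  Centring
at the placebo reference makes the fitted intercept the confounder-adjusted
placebo mean, which is what the intercept method back-transforms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .io import MethylationMatrix
from .transforms import clamp_beta, intercept_method

METHOD_GAUSSIAN_BETA = "gaussian_beta"
METHOD_BETA_REGRESSION = "beta_regression"
METHOD_RAW_BETA_DIFF = "raw_beta_diff"
METHOD_M_INTERCEPT = "m_regression_intercept"

RESULT_COLUMNS = [
    "cpg_id", "method", "intercept", "coef_treatment", "coef_age", "coef_sex",
    "p_value", "converged", "estimand", "estimand_kind",
]

_ALLOWED_ADJUST = ("age", "sex")


def _treatment_indicator(metadata: pd.DataFrame) -> tuple[np.ndarray, str]:
    levels = sorted(metadata["group"].astype(str).unique())
    if len(levels) != 2:
        raise InvalidInputError(f"need exactly two group levels, found {levels}")
    reference = "Placebo" if "Placebo" in levels else levels[0]
    treatment = [lv for lv in levels if lv != reference][0]
    return (metadata["group"].astype(str) == treatment).to_numpy(float), treatment


def build_design(
    metadata: pd.DataFrame, adjust: tuple[str, ...] = ()
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [1, treatment, *covariates] with placebo-centred coding."""
    unknown = [a for a in adjust if a not in _ALLOWED_ADJUST]
    if unknown:
        raise InvalidInputError(f"unknown adjustment covariates: {unknown}")
    grp, _ = _treatment_indicator(metadata)
    placebo = grp == 0.0
    cols = [np.ones(len(metadata)), grp]
    names = ["intercept", "treatment"]
    if "age" in adjust:
        age = metadata["age"].to_numpy(float)
        sd = age.std(ddof=1)
        if sd == 0:
            raise InvalidInputError("age has zero variance; cannot adjust for it")
        cols.append((age - age[placebo].mean()) / sd)
        names.append("age")
    if "sex" in adjust:
        sex = metadata["sex"].to_numpy(float)
        cols.append(sex - sex[placebo].mean())
        names.append("sex")
    return np.column_stack(cols), names


def _ols_mass_fit(X: np.ndarray, Y: np.ndarray):
    """OLS of every row of Y (n_cpg × n) on X (n × k).

    Returns (coefs, standard errors, p-values, fitted) or None when the
    design is rank deficient.
    """
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k or n <= k:
        return None
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ xtx_inv                      # n_cpg × k
    fitted = coefs @ X.T
    resid = Y - fitted
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = coefs / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    return coefs, se, pval, fitted


def _result_frame(
    matrix: MethylationMatrix,
    method: str,
    coefs: np.ndarray,
    pvals: np.ndarray,
    names: list[str],
    converged: np.ndarray,
    estimand: np.ndarray,
    estimand_kind: str,
) -> pd.DataFrame:
    def col(name: str) -> np.ndarray:
        if name in names:
            return coefs[:, names.index(name)]
        return np.full(len(matrix.cpg_ids), np.nan)

    return pd.DataFrame(
        {
            "cpg_id": matrix.cpg_ids,
            "method": method,
            "intercept": col("intercept"),
            "coef_treatment": col("treatment"),
            "coef_age": col("age"),
            "coef_sex": col("sex"),
            "p_value": pvals,
            "converged": converged,
            "estimand": estimand,
            "estimand_kind": estimand_kind,
        }
    )[RESULT_COLUMNS]


def fit_gaussian_beta(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    adjust: tuple[str, ...] = (),
) -> pd.DataFrame:
    """OLS on Beta-values; estimand is the treatment coefficient (ΔBeta).

    Linear-on-Beta fits can predict outside [0, 1]; offending CpGs are
    flagged in the ``pred_out_of_range`` column rather than rejected.
    """
    if matrix.scale != "beta":
        raise InvalidInputError("fit_gaussian_beta expects a beta-scale matrix")
    X, names = build_design(metadata, adjust)
    Y = matrix.values.to_numpy(float)
    fit = _ols_mass_fit(X, Y)
    if fit is None:
        out = _empty_failure(matrix, METHOD_GAUSSIAN_BETA, "difference")
        out["pred_out_of_range"] = False
        return out
    coefs, _, pvals, fitted = fit
    ok = np.isfinite(coefs).all(axis=1)
    out = _result_frame(
        matrix, METHOD_GAUSSIAN_BETA, coefs, pvals[:, names.index("treatment")],
        names, ok, np.where(ok, coefs[:, names.index("treatment")], np.nan),
        "difference",
    )
    out["pred_out_of_range"] = (fitted < 0.0).any(axis=1) | (fitted > 1.0).any(axis=1)
    return out


def fit_m_with_intercept(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    adjust: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """OLS on M-values, keeping the intercept; estimand via intercept method.

    The intercept — the confounder-adjusted placebo-group M mean under the
    placebo-centred coding — and intercept + treatment coefficient are
    back-transformed to the Beta scale and differenced, giving the
    confounder-adjusted ΔBeta.
    """
    if matrix.scale != "m":
        raise InvalidInputError("fit_m_with_intercept expects an m-scale matrix")
    X, names = build_design(metadata, adjust)
    Y = matrix.values.to_numpy(float)
    fit = _ols_mass_fit(X, Y)
    if fit is None:
        return _empty_failure(matrix, METHOD_M_INTERCEPT, "difference")
    coefs, _, pvals, _ = fit
    i0, i1 = names.index("intercept"), names.index("treatment")
    ok = np.isfinite(coefs).all(axis=1)
    estimand = np.array(
        [
            intercept_method(b0, b1).delta_beta if good else np.nan
            for b0, b1, good in zip(coefs[:, i0], coefs[:, i1], ok)
        ]
    )
    return _result_frame(
        matrix, METHOD_M_INTERCEPT, coefs, pvals[:, i1], names, ok, estimand,
        "difference",
    )


def raw_beta_diff(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    clamp_eps: float = 1e-6,
) -> pd.DataFrame:
    """Difference of raw group Beta means, with p-values from the M scale.

    This mirrors the common practice of testing on M-values but reporting
    unadjusted Beta-value mean differences.  No covariate adjustment by
    construction — that is the point of studying its bias.
    """
    if matrix.scale != "beta":
        raise InvalidInputError("raw_beta_diff expects a beta-scale matrix")
    grp, _ = _treatment_indicator(metadata)
    if grp.sum() == 0 or grp.sum() == len(grp):
        raise InvalidInputError("both groups must be non-empty")
    Y = matrix.values.to_numpy(float)
    diff = Y[:, grp == 1.0].mean(axis=1) - Y[:, grp == 0.0].mean(axis=1)

    m_companion = fit_m_with_intercept(
        matrix.to_scale("m", clamp_eps=clamp_eps), metadata, adjust=()
    )
    out = _result_frame(
        matrix, METHOD_RAW_BETA_DIFF,
        np.column_stack([np.full(len(diff), np.nan), diff]),
        m_companion["p_value"].to_numpy(),
        ["intercept", "treatment"],
        m_companion["converged"].to_numpy(),
        diff, "difference",
    )
    out["intercept"] = np.nan
    return out


def fit_beta_regression(
    matrix: MethylationMatrix,
    metadata: pd.DataFrame,
    adjust: tuple[str, ...] = (),
    clamp_eps: float = 1e-6,
    maxiter: int = 200,
) -> pd.DataFrame:
    """Beta regression per CpG; estimand is a methylation-odds ratio.

    Maximum likelihood with a natural-log logit mean link and a constant
    precision, fitted by Newton-Raphson on the observed Hessian (at most
    ``maxiter`` iterations).  ``converged`` is False when the optimiser
    fails, the Hessian is singular, or any estimate/standard error is
    non-finite — which happens systematically for means near the 0/1
    boundary; those rows carry no estimand but are always reported.
    """
    from statsmodels.othermod.betareg import BetaModel

    if matrix.scale != "beta":
        raise InvalidInputError("fit_beta_regression expects a beta-scale matrix")
    X, names = build_design(metadata, adjust)
    Y = clamp_beta(matrix.values.to_numpy(float), clamp_eps)
    k = len(names)

    coefs = np.full((len(matrix.cpg_ids), k), np.nan)
    pvals = np.full(len(matrix.cpg_ids), np.nan)
    ok = np.zeros(len(matrix.cpg_ids), dtype=bool)
    for i, y in enumerate(np.atleast_2d(Y)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = BetaModel(y, X).fit(method="newton", maxiter=maxiter, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
            finite = bool(
                np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse))
            )
            if converged and finite:
                coefs[i] = res.params[:k]
                pvals[i] = res.pvalues[names.index("treatment")]
                ok[i] = True
        except Exception:
            pass  # non-convergence is data, recorded below

    estimand = np.where(ok, np.exp(coefs[:, names.index("treatment")]), np.nan)
    return _result_frame(
        matrix, METHOD_BETA_REGRESSION, coefs, pvals, names, ok, estimand,
        "odds_ratio",
    )


def adjust_pvalues(results: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Append a multiplicity-adjusted p-value column (Benjamini-Hochberg)."""
    from statsmodels.stats.multitest import multipletests

    out = results.copy()
    mask = out["p_value"].notna().to_numpy()
    p_adj = np.full(len(out), np.nan)
    if mask.any():
        p_adj[mask] = multipletests(out.loc[mask, "p_value"], method=method)[1]
    out["p_adj"] = p_adj
    return out


def _empty_failure(
    matrix: MethylationMatrix, method: str, kind: str
) -> pd.DataFrame:
    n = len(matrix.cpg_ids)
    nan = np.full(n, np.nan)
    return _result_frame(
        matrix, method, np.column_stack([nan, nan]), nan,
        ["intercept", "treatment"], np.zeros(n, dtype=bool), nan, kind,
    )
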