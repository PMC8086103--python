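"""Scalar/array transforms between intensities, Beta-values and M-values.

Beta-values are methylation fractions in [0, 1); M-values are their base-2
logit, approximately normal and unbounded.  Two different logits coexist in
this package and are named apart deliberately:

* the *M-logit* ``log2(b / (1 - b))`` used by :func:`beta_to_m`, and
* the natural-log logit whose inverse is :func:`inverse_logit`
  (``exp(x) / (1 + exp(x))``), used to back-transform beta-regression
  coefficients.

All transforms accept scalars or array-likes and preserve shape; scalar in,
scalar out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError

#: Default half-width by which Beta-values are kept away from {0, 1} before
#: the logit.  Eq-1-style Beta-values never reach 1, but values read from
#: processed files can touch both ends.
DEFAULT_CLAMP_EPS = 1e-6

#: Default intensity offset in the Beta-value denominator.
DEFAULT_OFFSET = 100.0


def _as_array(x, name: str) -> tuple[np.ndarray, bool]:
    """Validate finiteness and return (array, was_scalar)."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {x!r}")
    return arr, arr.ndim == 0


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def clamp_beta(beta, clamp_eps: float = DEFAULT_CLAMP_EPS):
    """Clamp Beta-values into ``[clamp_eps, 1 - clamp_eps]``.

    Values outside [0, 1] are rejected rather than clamped: they indicate a
    unit error upstream, not boundary methylation.
    """
    arr, scalar = _as_array(beta, "beta")
    if np.any(arr < 0) or np.any(arr > 1):
        bad = arr[(arr < 0) | (arr > 1)]
        raise InvalidInputError(f"beta values outside [0, 1]: {bad[:5]!r}")
    if not 0 < clamp_eps < 0.5:
        raise InvalidInputError(f"clamp_eps must be in (0, 0.5), got {clamp_eps}")
    return _maybe_scalar(np.clip(arr, clamp_eps, 1.0 - clamp_eps), scalar)


def intensities_to_beta(methylated, unmethylated, offset: float = DEFAULT_OFFSET):
    """Beta-value from methylated/unmethylated probe intensities.

    ``max(meth, 0) / (max(meth, 0) + max(unmeth, 0) + offset)``.  Negative
    intensities (background-corrected signals) are clamped to zero; the
    positive offset keeps the result strictly below 1.
    """
    m_arr, m_scalar = _as_array(methylated, "methylated")
    u_arr, u_scalar = _as_array(unmethylated, "unmethylated")
    if offset < 0 or not np.isfinite(offset):
        raise InvalidInputError(f"offset must be a finite non-negative number, got {offset}")
    m = np.maximum(m_arr, 0.0)
    u = np.maximum(u_arr, 0.0)
    beta = m / (m + u + offset)
    return _maybe_scalar(beta, m_scalar and u_scalar)


def beta_to_m(beta, clamp_eps: float = DEFAULT_CLAMP_EPS):
    """M-value (base-2 logit) of a Beta-value.

    ``log2(b / (1 - b))`` after clamping ``b`` into
    ``[clamp_eps, 1 - clamp_eps]``.  Strictly increasing and antisymmetric
    about b = 0.5 (``beta_to_m(1 - b) == -beta_to_m(b)``).
    """
    arr, scalar = _as_array(beta, "beta")
    b = clamp_beta(arr, clamp_eps)
    b = np.asarray(b, dtype=float)
    return _maybe_scalar(np.log2(b) - np.log2(1.0 - b), scalar)


def m_to_beta(m):
    """Beta-value from an M-value: ``2**m / (1 + 2**m)``.

    Exact inverse of :func:`beta_to_m` on the clamped domain.  Implemented
    through the logistic function at base e for numerical stability at large
    ``|m|``; the result lies strictly in (0, 1).
    """
    arr, scalar = _as_array(m, "m")
    return _maybe_scalar(expit(arr * np.log(2.0)), scalar)


def inverse_logit(x):
    """Natural-log inverse logit ``exp(x) / (1 + exp(x))``.

    This is the back-transform for beta-regression coefficients (natural-log
    link), *not* the inverse of the base-2 M-logit; see :func:`m_to_beta`
    for that.  Saturates smoothly to 0/1 without under- or overflow.
    """
    arr, scalar = _as_array(x, "x")
    return _maybe_scalar(expit(arr), scalar)


@dataclass(frozen=True)
class EstimandRecord:
    """A reportable effect on the Beta scale with its M-scale companion.

    ``kind="difference"`` records a difference of Beta-values in (-1, 1);
    ``kind="odds_ratio"`` records a strictly positive methylation-odds
    ratio (the beta-regression estimand).
    """

    delta_beta: float | None
    delta_m: float | None
    kind: Literal["difference", "odds_ratio"]

    def __post_init__(self) -> None:
        if self.kind not in ("difference", "odds_ratio"):
            raise InvalidInputError(f"unknown estimand kind {self.kind!r}")
        if self.kind == "difference" and self.delta_beta is not None:
            if not -1.0 < self.delta_beta < 1.0:
                raise InvalidInputError(
                    f"difference estimand must lie in (-1, 1), got {self.delta_beta}"
                )
        if self.kind == "odds_ratio" and self.delta_beta is not None:
            if self.delta_beta <= 0:
                raise InvalidInputError(
                    f"odds-ratio estimand must be positive, got {self.delta_beta}"
                )


def intercept_method(intercept_m, coef_m) -> EstimandRecord:
    """Confounder-adjusted difference in Beta-values from an M-scale fit.

    Back-transforms the intercept (the adjusted placebo-group mean M-value)
    and intercept + treatment coefficient separately and differences them:

    ``delta_beta = m_to_beta(intercept_m + coef_m) - m_to_beta(intercept_m)``

    This is the only faithful route from an M-scale regression effect to a
    Beta-scale difference: the coefficient alone does not determine the
    difference because the M→Beta map is nonlinear.
    """
    b0, s0 = _as_array(intercept_m, "intercept_m")
    b1, s1 = _as_array(coef_m, "coef_m")
    if not (s0 and s1):
        raise InvalidInputError("intercept_method expects scalar inputs")
    delta = m_to_beta(float(b0) + float(b1)) - m_to_beta(float(b0))
    return EstimandRecord(delta_beta=delta, delta_m=float(b1), kind="difference")
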