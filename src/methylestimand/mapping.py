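"""The non-bijective ΔM ↔ ΔBeta relationship and the worked-example table.

A single difference in M-values is compatible with a whole interval of
differences in Beta-values ("mustache" envelope): for a fixed ΔM the
attained ΔBeta depends on where the baseline Beta-value sits.  The maximum
has a closed form — the M pair symmetric about zero — while the minimum is
reached at the extremes of the admissible Beta range and therefore depends
on how close to 0/1 one allows the baseline to go.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyEnvelopeError, InvalidInputError
from .transforms import beta_to_m, m_to_beta

#: Default baseline-Beta bounds and grid size for the envelope sweep.
DEFAULT_BETA_LO = 0.001
DEFAULT_BETA_HI = 0.999
DEFAULT_GRID_N = 100_000


@dataclass(frozen=True)
class DeltaEnvelope:
    """Attainable ΔBeta interval for a fixed non-negative ΔM."""

    delta_m: float
    min_delta_beta: float
    max_delta_beta: float

    def contains(self, delta_beta: float, atol: float = 1e-9) -> bool:
        return (
            self.min_delta_beta - atol <= delta_beta <= self.max_delta_beta + atol
        )


def delta_beta_max(delta_m) -> float:
    """Largest ΔBeta attainable for a given non-negative ΔM (closed form).

    The maximizing Beta pair is the one whose M-values sit symmetrically
    about 0, i.e. ``m_to_beta(dm/2) - m_to_beta(-dm/2)``.
    """
    arr = np.asarray(delta_m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"delta_m must be finite, got {delta_m!r}")
    if np.any(arr < 0):
        raise InvalidInputError(f"delta_m must be non-negative, got {delta_m!r}")
    out = m_to_beta(arr / 2.0) - m_to_beta(-arr / 2.0)
    return float(out) if arr.ndim == 0 else out


def delta_beta_range(
    delta_m: float,
    beta_lo: float = DEFAULT_BETA_LO,
    beta_hi: float = DEFAULT_BETA_HI,
    grid_n: int = DEFAULT_GRID_N,
) -> DeltaEnvelope:
    """Attainable ΔBeta interval for ΔM by sweeping the baseline Beta.

    Sweeps baseline ``b`` over a uniform grid on [beta_lo, beta_hi], pairs
    it with ``m_to_beta(beta_to_m(b) + delta_m)`` and keeps pairs whose
    partner stays at or below ``beta_hi``.  The envelope is computed for
    ``|delta_m|``; the relationship is symmetric in the sign.

    Raises :class:`EmptyEnvelopeError` when no baseline on the grid admits
    a partner inside the bounds (ΔM too large for the allowed range).
    """
    if not np.isfinite(delta_m):
        raise InvalidInputError(f"delta_m must be finite, got {delta_m!r}")
    dm = abs(float(delta_m))
    if not (0.0 < beta_lo < beta_hi < 1.0):
        raise InvalidInputError(
            f"need 0 < beta_lo < beta_hi < 1, got ({beta_lo}, {beta_hi})"
        )
    if grid_n < 2:
        raise InvalidInputError(f"grid_n must be at least 2, got {grid_n}")
    base = np.linspace(beta_lo, beta_hi, int(grid_n))
    partner = m_to_beta(beta_to_m(base, clamp_eps=min(1e-12, beta_lo / 2)) + dm)
    keep = partner <= beta_hi
    if not np.any(keep):
        raise EmptyEnvelopeError(
            f"no Beta pair within [{beta_lo}, {beta_hi}] attains delta_m={dm}"
        )
    diffs = partner[keep] - base[keep]
    return DeltaEnvelope(
        delta_m=dm,
        min_delta_beta=float(diffs.min()),
        max_delta_beta=float(diffs.max()),
    )


def table4(
    beta_baselines=(0.001, 0.101, 0.201, 0.301, 0.401, 0.501, 0.601, 0.701, 0.801, 0.901),
    delta_beta: float = 0.10,
    boundary_cap: float | None = 0.999,
) -> pd.DataFrame:
    """Worked-example table: a constant ΔBeta maps to many different ΔM.

    One row per placebo baseline.  M-value columns are rounded to 2 dp and
    back-transformed Beta columns to 3 dp for display, matching common
    reporting precision; ``delta_m`` carries full precision while
    ``delta_m_printed`` is the difference of the *rounded* group M-values —
    the quantity a reader reconstructs from a printed table.

    A baseline whose treatment value would reach 1 is mirror-capped at
    ``boundary_cap`` (so the default grid ends 0.901 → 0.999, symmetric
    with the opening 0.001 → 0.101 row, and the actual difference 0.098
    still prints as 0.10); such rows carry ``capped=True``.  With
    ``boundary_cap=None`` they are flagged invalid instead.
    """
    baselines = np.asarray(beta_baselines, dtype=float)
    if baselines.ndim != 1 or len(baselines) == 0:
        raise InvalidInputError("beta_baselines must be a non-empty 1-D collection")
    if np.any(baselines <= 0) or np.any(baselines >= 1):
        raise InvalidInputError("all baselines must lie strictly in (0, 1)")
    if boundary_cap is not None and not 0.0 < boundary_cap < 1.0:
        raise InvalidInputError(f"boundary_cap must be in (0, 1), got {boundary_cap}")

    rows = []
    for b_pl in baselines:
        b_tr = b_pl + delta_beta
        capped = False
        if b_tr >= 1.0 and boundary_cap is not None and boundary_cap > b_pl:
            b_tr = boundary_cap
            capped = True
        valid = 0.0 < b_tr < 1.0
        if valid:
            m_pl = beta_to_m(b_pl)
            m_tr = beta_to_m(b_tr)
            dm = m_tr - m_pl
            dm_printed = round(m_tr, 2) - round(m_pl, 2)
            formula = f"{m_pl:.2f} + {dm_printed:.2f} · Grp_Treatment"
        else:
            m_pl = beta_to_m(b_pl)
            m_tr = dm = dm_printed = np.nan
            formula = ""
        rows.append(
            {
                "beta_placebo": b_pl,
                "m_placebo": m_pl,
                "beta_treatment": b_tr if valid else np.nan,
                "m_treatment": m_tr,
                "delta_beta": (b_tr - b_pl) if valid else np.nan,
                "delta_m": dm,
                "delta_m_printed": round(dm_printed, 2) if valid else np.nan,
                "regression_formula": formula,
                "capped": capped,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)
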