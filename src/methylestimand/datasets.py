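"""Synthetic EWAS cohorts with known generative truth.

The generator mirrors the two-group design the bias studies assume.  A
predefined treatment effect is specified as a difference in Beta-values
(the biologically meaningful scale), mapped to the M scale through the
base-2 logit, and realised as a Gaussian linear model on M-values:

    M = β0 + β1·Grp + β3·(Age − Age_placebo) + β4·(Sex − p_placebo) + ε

with β0 the placebo-group M mean, ε ~ N(0, noise_sd_m²).  A confounder
fraction ``c`` diverts part of the total between-group M difference from
the treatment coefficient to group-imbalanced Age and Sex covariates:
β1 = (1 − c)·ΔM_total while the covariate terms contribute the remaining
c·ΔM_total in expectation, in the same direction as the treatment effect.
The raw between-group difference therefore equals ΔM_total regardless of
``c`` — only its attribution changes, which is exactly what a naive
unadjusted estimate cannot see.

Covariates are centred at their placebo population values in the linear
predictor so that β0 remains the placebo mean whatever ``c`` is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .io import MethylationMatrix
from .transforms import beta_to_m, m_to_beta

# Fixed covariate distributions: Age in years, Sex as a 0/1 indicator.
# The group imbalance (older, more often sex=1 under treatment) is what
# lets nonzero coefficients act as genuine confounders.
AGE_MEAN_PLACEBO = 50.0
AGE_MEAN_TREATMENT = 55.0
AGE_SD = 8.0
SEX_P_PLACEBO = 0.3
SEX_P_TREATMENT = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for a two-group methylation cohort.

    ``confounder_fraction`` is the share of the total M-scale group
    difference carried by Age and Sex together; ``confounder_split`` is
    Age's share of that (the rest goes to Sex).  ``noise_sd_m`` is the
    residual SD of the M-values.  ``beta_precision`` is the precision
    (shape sum) of the beta distribution used when the outcome is drawn
    on the Beta scale directly.
    """

    n_per_group: int = 500
    beta0_placebo: float = 0.3
    delta_beta: float = 0.1
    confounder_fraction: float = 0.0
    confounder_split: float = 0.5
    noise_sd_m: float = 0.5
    beta_precision: float = 30.0
    n_cpg: int = 1
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_cpg < 1 or self.n_sims < 1:
            raise InvalidConfigError("all counts must be >= 1")
        if not 0.0 <= self.confounder_fraction < 1.0:
            raise InvalidConfigError(
                f"confounder_fraction must be in [0, 1), got {self.confounder_fraction}"
            )
        if not 0.0 <= self.confounder_split <= 1.0:
            raise InvalidConfigError(
                f"confounder_split must be in [0, 1], got {self.confounder_split}"
            )
        if not 0.0 < self.beta0_placebo < 1.0:
            raise InvalidConfigError(
                f"beta0_placebo must be in (0, 1), got {self.beta0_placebo}"
            )
        if not 0.0 < self.beta0_placebo + self.delta_beta < 1.0:
            raise InvalidConfigError(
                "beta0_placebo + delta_beta must stay inside (0, 1), got "
                f"{self.beta0_placebo + self.delta_beta}"
            )
        if self.noise_sd_m <= 0 or self.beta_precision <= 0:
            raise InvalidConfigError("noise_sd_m and beta_precision must be positive")


@dataclass(frozen=True)
class CohortTruth:
    """What the generator actually put into a cohort."""

    delta_beta_true: float          # predefined Beta-scale group difference
    delta_m_total: float            # total M-scale group difference
    delta_m_treatment: float        # treatment-attributable part, (1-c)*total
    delta_m_age: float              # expected Age contribution
    delta_m_sex: float              # expected Sex contribution
    coef_age: float                 # β3 per year
    coef_sex: float                 # β4 per indicator unit
    beta0_placebo: float
    m0_placebo: float
    confounder_fraction: float
    noise_sd_m: float

    @property
    def delta_beta_treatment(self) -> float:
        """Treatment-attributable ΔBeta: the adjusted-estimand target."""
        return m_to_beta(self.m0_placebo + self.delta_m_treatment) - m_to_beta(
            self.m0_placebo
        )


def _metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_per_group
    group = np.repeat(["Placebo", "Treatment"], n)
    age = np.where(
        group == "Placebo",
        rng.normal(AGE_MEAN_PLACEBO, AGE_SD, 2 * n),
        rng.normal(AGE_MEAN_TREATMENT, AGE_SD, 2 * n),
    )
    sex = np.where(
        group == "Placebo",
        rng.binomial(1, SEX_P_PLACEBO, 2 * n),
        rng.binomial(1, SEX_P_TREATMENT, 2 * n),
    )
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(2 * n)],
            "group": group,
            "age": age,
            "sex": sex,
        }
    )


def cohort_truth(config: SimulationConfig) -> CohortTruth:
    """Deterministic generative truth implied by a configuration."""
    m0 = beta_to_m(config.beta0_placebo)
    dm_total = beta_to_m(config.beta0_placebo + config.delta_beta) - m0
    c = config.confounder_fraction
    dm_age = c * config.confounder_split * dm_total
    dm_sex = c * (1.0 - config.confounder_split) * dm_total
    return CohortTruth(
        delta_beta_true=config.delta_beta,
        delta_m_total=dm_total,
        delta_m_treatment=(1.0 - c) * dm_total,
        delta_m_age=dm_age,
        delta_m_sex=dm_sex,
        coef_age=dm_age / (AGE_MEAN_TREATMENT - AGE_MEAN_PLACEBO),
        coef_sex=dm_sex / (SEX_P_TREATMENT - SEX_P_PLACEBO),
        beta0_placebo=config.beta0_placebo,
        m0_placebo=m0,
        confounder_fraction=c,
        noise_sd_m=config.noise_sd_m,
    )


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[MethylationMatrix, pd.DataFrame, CohortTruth]:
    """Draw an M-scale cohort: matrix (n_cpg × samples), metadata, truth."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    truth = cohort_truth(config)
    meta = _metadata(config, rng)
    grp = (meta["group"] == "Treatment").to_numpy(float)
    linpred = (
        truth.m0_placebo
        + truth.delta_m_treatment * grp
        + truth.coef_age * (meta["age"].to_numpy() - AGE_MEAN_PLACEBO)
        + truth.coef_sex * (meta["sex"].to_numpy() - SEX_P_PLACEBO)
    )
    noise = rng.normal(0.0, config.noise_sd_m, size=(config.n_cpg, len(meta)))
    values = pd.DataFrame(
        linpred[None, :] + noise,
        index=[f"cg{i + 1:06d}" for i in range(config.n_cpg)],
        columns=meta["sample_id"],
    )
    return MethylationMatrix(values, "m"), meta, truth


def simulate_beta_outcome(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Draw a Beta-scale cohort from beta distributions with group means.

    Placebo mean = ``beta0_placebo``, treatment mean = baseline + effect,
    common precision ``beta_precision``.  Used by the beta-regression
    convergence study, where the distributional boundary matters.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    meta = _metadata(config, rng)
    mu = np.where(
        meta["group"] == "Treatment",
        config.beta0_placebo + config.delta_beta,
        config.beta0_placebo,
    )
    phi = config.beta_precision
    draws = rng.beta(mu * phi, (1.0 - mu) * phi, size=(config.n_cpg, len(meta)))
    # beta draws with tiny shape parameters can underflow to exactly 0
    tiny = np.finfo(float).tiny
    draws = np.clip(draws, tiny, 1.0 - 1e-16)
    values = pd.DataFrame(
        draws,
        index=[f"cg{i + 1:06d}" for i in range(config.n_cpg)],
        columns=meta["sample_id"],
    )
    return MethylationMatrix(values, "beta"), meta


def fixture_matrix(
    n_cpg: int,
    n_samples: int,
    boundary_mass: float = 0.5,
    rng: np.random.Generator | int | None = None,
    precision: float = 30.0,
) -> MethylationMatrix:
    """Beta-scale matrix emulating the shape of processed array data.

    A ``boundary_mass`` fraction of CpG rows is hypo- (mean near 0) or
    hypermethylated (mean near 1), split evenly; the rest sit mid-range.
    Per-row values are beta draws around the row mean, so the M-transform
    of each row is roughly normal.
    """
    if not 0.0 <= boundary_mass <= 1.0:
        raise InvalidConfigError(f"boundary_mass must be in [0, 1], got {boundary_mass}")
    rng = np.random.default_rng(rng)
    n_boundary = int(round(boundary_mass * n_cpg))
    n_hypo = n_boundary // 2
    n_hyper = n_boundary - n_hypo
    n_mid = n_cpg - n_boundary
    means = np.concatenate(
        [
            rng.uniform(0.02, 0.08, n_hypo),
            rng.uniform(0.25, 0.75, n_mid),
            rng.uniform(0.92, 0.98, n_hyper),
        ]
    )
    rng.shuffle(means)
    draws = rng.beta(
        means[:, None] * precision, (1.0 - means[:, None]) * precision,
        size=(n_cpg, n_samples),
    )
    tiny = np.finfo(float).tiny
    draws = np.clip(draws, tiny, 1.0 - 1e-16)
    values = pd.DataFrame(
        draws,
        index=[f"cg{i + 1:06d}" for i in range(n_cpg)],
        columns=[f"S{j + 1:04d}" for j in range(n_samples)],
    )
    return MethylationMatrix(values, "beta")
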