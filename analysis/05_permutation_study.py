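#!/usr/bin/env python
"""Null ΔM/ΔBeta pairs from random group assignment.

Takes a synthetic Beta-value matrix shaped like processed array data (half
of the CpG rows hypo- or hypermethylated) and repeatedly assigns disjoint
random "treatment"/"placebo" groups of size 5–100.  Per CpG the difference
of group M-value means and the difference of the back-transformed group
means are recorded.  The observed pairs trace out the theoretical envelope:
small groups generate the widest ΔM ranges, every pair stays inside the
ΔBeta bound implied by its ΔM, and boundary CpG rows produce large ΔM with
tiny ΔBeta.
"""

import argparse
import pathlib

from methylestimand import (
    delta_beta_max,
    envelope_violations,
    fixture_matrix,
    run_permutation_study,
)

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--reps", type=int, default=200)
    parser.add_argument("--n-cpg", type=int, default=200)
    args = parser.parse_args()

    matrix = fixture_matrix(args.n_cpg, 220, boundary_mass=0.5, rng=args.seed)
    records, hist = run_permutation_study(
        matrix, group_sizes=(5, 10, 20, 50, 100), n_reps=args.reps, rng=args.seed
    )

    summary = (
        records.groupby("group_size")
        .agg(
            max_abs_delta_m=("delta_m", lambda s: s.abs().max()),
            q99_abs_delta_m=("delta_m", lambda s: s.abs().quantile(0.99)),
            max_abs_delta_beta=("delta_beta", lambda s: s.abs().max()),
        )
        .round(4)
        .reset_index()
    )
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out = results / "permutation_summary.csv"
    summary.to_csv(out, index=False)
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    records.round(6).to_csv(scratch / "permutation_records.csv", index=False)

    print(summary.to_string(index=False))
    violations = envelope_violations(records)
    widest = records.loc[records["delta_m"].abs().idxmax()]
    print(f"\nEnvelope violations: {violations} of {len(records)} pairs.")
    print(f"Widest observed |ΔM| = {abs(widest['delta_m']):.2f} carries "
          f"ΔBeta = {widest['delta_beta']:+.4f} "
          f"(theoretical bound ±{delta_beta_max(abs(widest['delta_m'])):.4f}).")
    print("Small groups of 5 produce several-fold wider null ΔM ranges than "
          "groups of 100 — yet the same ΔM can mean a negligible ΔBeta.")
    print(f"Wrote {out}")


if __name__ == "__main__":
    main()
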