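# methylestimand

Estimand-correct effect reporting for differential DNA methylation
analysis.

EWAS pipelines test on **M-values** (the base-2 logit of the methylation
fraction, approximately normal) but biologists need effects on the
**Beta-value** scale (percent methylation, directly interpretable). The
two scales convert exactly pointwise — `M = log2(B/(1−B))`,
`B = 2^M/(1+2^M)` — but *differences* do not: one ΔM is compatible with a
whole interval of ΔBeta depending on the baseline, and the popular
shortcut of taking p-values from M-values while reporting raw Beta-value
mean differences silently drops confounder adjustment. This package, for
methylation analysts and methods developers, provides:

- the exact transformation algebra between intensities, Beta- and
  M-values (two logits, named apart);
- the **intercept method**: from a covariate-adjusted M-scale regression
  `M = β0 + β1·Grp + β3·Age + β4·Sex + ε` with placebo-centred
  covariates, the confounder-adjusted difference in Beta-values is
  `ΔBeta = 2^(β0+β1)/(1+2^(β0+β1)) − 2^β0/(1+2^β0)`;
- the ΔM↔ΔBeta envelope ("mustache"): closed-form maximum
  `m_to_beta(ΔM/2) − m_to_beta(−ΔM/2)` plus a grid-searched minimum;
- per-CpG implementations of four reporting approaches (Gaussian on
  Beta, beta regression with odds-ratio estimand, raw Beta difference,
  M-regression + intercept method), with honest convergence accounting;
- a synthetic-cohort generator with a tunable confounder fraction and
  the simulation studies that quantify each approach's bias.

## Worked example

```python
>>> from methylestimand import beta_to_m, m_to_beta, intercept_method, table4
>>> round(beta_to_m(0.101), 2)          # placebo group mean on the M scale
-3.15
>>> round(m_to_beta(-3.15 + 1.16), 3)   # treatment mean, back-transformed
0.201
>>> intercept_method(-3.15, 1.16).delta_beta   # adjusted ΔBeta
0.09986147083787901
```

A fitted M-scale model `−3.15 + 1.16·Grp_Treatment` therefore reports a
10-percentage-point methylation increase. The same ΔBeta of 0.10 maps to
wildly different ΔM depending on the baseline — `table4()` reproduces the
full correspondence; `analysis/01_worked_example_table.py` prints it:

```
 beta_placebo  m_placebo  beta_treatment  m_treatment  delta_m_printed
        0.001      -9.96           0.101        -3.15             6.81
        0.101      -3.15           0.201        -1.99             1.16
        0.401      -0.58           0.501         0.01             0.59
        0.901       3.19           0.999         9.96             6.77
ΔM spans 0.58–6.81 (11.6-fold) for a single ΔBeta of 0.10.
```

so an M-scale coefficient is meaningless as an effect size without its
intercept. Conversely ΔM = 5 admits any ΔBeta between ≈ 0.03 and 0.6996
(`delta_beta_max(5)`).

## The analysis suite

Numbered drivers under `analysis/` rerun the package's studies and write
tables to `results/` (all take `--seed`):

1. `01_worked_example_table.py` — the constant-ΔBeta table above.
2. `02_mustache_envelope.py` — ΔBeta envelope for ΔM ∈ [0, 10].
3. `03_bias_study.py` — percent deviation of the raw Beta difference vs
   the intercept method when age/sex confounders carry 0/10/20% of the
   effect. Headline numbers: raw differences off by **7–16%** (c = 0.10)
   and **19–37%** (c = 0.20) while the intercept method stays within
   Monte-Carlo noise of its target.
4. `04_convergence_study.py` — beta-regression convergence collapses for
   placebo means ≤ 0.01 (rate 0.00) and is 1.00 from 0.1 onwards:
   hypo-/hypermethylated CpG sites need the intercept method instead.
5. `05_permutation_study.py` — null ΔM/ΔBeta pairs from random group
   assignment on an array-shaped synthetic matrix; all 200 000 pairs fall
   inside the theoretical envelope, and group size 5 produces the widest
   ΔM ranges (|ΔM| up to ≈ 6.8 with ΔBeta ≈ 0.02 at boundary CpGs).

A `methylestimand` CLI exposes the same operations
(`transform`, `simulate`, `fit`, `bias-study`, `convergence`, `permute`,
`mustache`, `table4`); every run logs its parameters and seed to stderr.

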