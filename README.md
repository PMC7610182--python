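# smokemr

Two-sample Mendelian randomisation (MR) tooling for studying the causal
relationship between lifetime smoking and psychiatric outcomes
(schizophrenia, major depression), built around a **lifetime smoking index**
that folds smoking duration, intensity and time since cessation into a single
continuous exposure usable in never-smoker-inclusive GWAS.

## The model

For an individual with smoking duration `dur` (years), time since cessation
`tsc` (years, 0 for current smokers) and intensity `cpd` (cigarettes per
day), the index is

```
score = (1 − 0.5^(dur/τ)) · 0.5^(tsc/τ) · ln(cpd + 1)
```

with a single half-life parameter τ (default 18 years) governing both how
quickly risk accumulates while smoking and how quickly it decays after
quitting. Never smokers score exactly 0. Two reference histories each equal
to one cohort standard deviation of the score:

* 15 years' smoking, quit 17 years ago, 20 cpd → **0.694**
* 13 years' smoking, quit 22 years ago, 60 cpd → **0.694**

On top of the index, the package provides:

* **`smoking_index`** — score computation, cohort scoring, and data-driven
  calibration of τ by grid-scan against a health outcome (logistic or Cox
  criterion).
* **`summary_stats`** — GWAS summary-statistic ingestion with flexible column
  mapping, genome-wide-significance instrument selection with clumping,
  allele harmonisation (strand flips, swaps, palindromic-SNP frequency
  alignment with a MAF < 0.3 rule) and LD-proxy substitution. Every input
  SNP is either retained or dropped with a logged reason.
* **`mr_estimators`** — IVW (multiplicative random effects), MR-Egger with
  intercept test, weighted median, weighted mode, MR-RAPS (robust adjusted
  profile score with overdispersion), Wald ratios, Cochran's Q, I²GX, mean F,
  Steiger directionality filtering, and SIMEX-corrected Egger for weak
  instruments (I²GX < 0.9).
* **`synthetic_data`** — summary-statistic and individual-level cohort
  generators with known ground truth (configurable pleiotropy, weak
  instruments, allele-bookkeeping perturbations), used by the test suite.
* **`pipeline` / CLI** — bi-directional analysis orchestration with a YAML
  config, result tables, drop logs and a reproducibility manifest.

## Worked example

Score a small cohort file (TSV with columns
`id, status, cpd, age_init, age_cess, age_assess`):

```
$ smokemr index --histories cohort.tsv --tau 18
id      status  cpd     age_init        age_cess        age_assess      score
a       former  20.0    20.0    35.0    52      0.6941430573211523
b       current 10.0    30.0            50      1.287819974899748
c       never                           50      0.0
```

Simulate a two-sample design with known effect and run the full estimator
battery:

```
$ smokemr simulate summary --seed 7 --out sim
wrote sim/exposure.tsv, outcome.tsv, truth.tsv
$ smokemr mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --outcome-type binary --direction forward --out-dir mr_out
== forward ==
method            nsnp       OR             95% CI          p
IVW                 30      1.6       (1.51, 1.69)   3.69e-16
Egger               30     1.76       (1.45, 2.12)   2.87e-06
weighted-median     30     1.61       (1.49, 1.73)    4.1e-36
weighted-mode       30     1.61       (1.43, 1.81)   2.65e-15
RAPS                30      1.6        (1.52, 1.7)   2.01e-62
```

(The generator's default true effect is 0.5 on the log-odds scale,
OR ≈ 1.65; all five estimators recover it.) `mr_out/` additionally contains
the full results, diagnostics, drop log and a `manifest.json` with the config
hash and package versions. The same analysis is available in Python via
`smokemr.run_pipeline(AnalysisConfig(...), out_dir)`.

Calibrate the half-life on a cohort:

```
$ smokemr calibrate --histories histories.tsv --outcome outcome.tsv --grid 2:40:2
```

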