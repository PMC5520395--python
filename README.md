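# adipomr

Two-sample Mendelian randomisation (MR) from GWAS summary statistics,
built for analyses of adiposity-related traits (BMI, childhood obesity,
central-obesity measures, adiponectin) against disease risk and
survival — the setting of multi-cohort myeloma case–control GWAS — but
applicable to any summary-level exposure/outcome pair.

MR uses genetic variants as instrumental variables for a modifiable
exposure: because alleles are randomised at meiosis, a variant robustly
associated with the exposure is free of the confounding and reverse
causation that limit observational epidemiology.  In the two-sample
design, SNP–exposure effects β<sub>X</sub> (in trait s.d. units) and
SNP–outcome effects β<sub>Y</sub> (log odds or log hazard ratios) come
from different studies and are combined per SNP as Wald ratios
β<sub>Y</sub>/β<sub>X</sub>, pooled by the fixed-effects
inverse-variance-weighted (IVW) estimator

&nbsp;&nbsp;&nbsp;&nbsp;θ̂ = Σ β<sub>X</sub>β<sub>Y</sub>/σ<sub>Y</sub>² ÷ Σ β<sub>X</sub>²/σ<sub>Y</sub>²,&nbsp;&nbsp; se(θ̂) = (Σ β<sub>X</sub>²/σ<sub>Y</sub>²)<sup>−1/2</sup>

— the summary-level equivalent of a genetic-risk-score two-stage
analysis.  The package provides:

* **io_summary** — tab-delimited readers/writers for instrument and
  outcome tables (configurable column names, lossless round-trips) and
  forest-plot data.
* **harmonization** — allele alignment across studies (sign flips,
  strand flips, frequency-based palindromic-SNP resolution) with a full
  per-SNP audit trail.
* **estimators** — Wald ratios, fixed-effects IVW (binary and survival
  scales), MR-Egger regression with pleiotropy intercept, Cochran's Q.
* **meta_analysis** — fixed-effects pooling of per-cohort estimates
  with between-cohort Q/I², and forest-plot rows.
* **power** — closed-form power of binary-outcome MR given sample
  composition, instrument r² and a postulated OR per s.d.
* **synthetic** — a summary-level generator with known causal ground
  truth: genome-wide-significant instruments, per-cohort outcome
  associations, balanced/directional pleiotropy (with or without the
  InSIDE condition), and per-cohort instrument dropout.
* **pipeline / CLI** — `adipomr simulate | harmonize | estimate | meta
  | power | run-all`, with deterministic seeds and a run manifest.

See `docs/methods.md` for the statistical details and the generator's
assumptions.

## Worked example

Simulate a five-cohort study (6 839 cases / 22 221 controls split
across UK, Germany, Netherlands, Sweden, USA) with 50 instruments and a
true causal effect of θ = 0.15 log-OR per exposure s.d., then analyse
it:

```python
from adipomr import (SimulationTruth, simulate_study, harmonize,
                     ivw_fixed_effects, meta_fixed, mr_egger, cochran_q,
                     mr_power, PowerScenario)
from adipomr.pipeline import pool_pairs_across_cohorts

truth = SimulationTruth(theta=0.15, n_snps=50, seed=42)
study = simulate_study(truth, trait="BMI")
pairs = harmonize(study.instruments, study.all_outcomes)

by_cohort = {}
for p in pairs:
    by_cohort.setdefault(p.cohort, []).append(p)
estimates = [ivw_fixed_effects(v) for v in by_cohort.values()]
for e in estimates:
    print(f"{e.cohort:12s} OR={e.ratio_scale:.3f} "
          f"({e.ci_low:.3f}-{e.ci_high:.3f}) p={e.pvalue:.3g}")
meta = meta_fixed(estimates)
print(f"pooled       OR={meta.or_pooled:.3f} "
      f"({meta.ci_low:.3f}-{meta.ci_high:.3f}) p={meta.pvalue:.3g}")

pooled = pool_pairs_across_cohorts(pairs)
q = cochran_q(pooled, ivw_fixed_effects(pooled))
egger = mr_egger(pooled)
print(f"Q={q.q_statistic:.1f} (df={q.df}) p={q.p_het:.2f}; "
      f"Egger intercept={egger.intercept:.4f} p={egger.p_intercept:.2f}")
print(f"power OR=1.2, r2=0.05: {mr_power(PowerScenario(6839, 22221, 0.05, 1.2)):.3f}")
```

prints

```
UK           OR=1.263 (1.024-1.558) p=0.0288
Germany      OR=0.983 (0.797-1.213) p=0.875
Netherlands  OR=1.276 (1.035-1.574) p=0.0227
Sweden       OR=1.240 (1.006-1.529) p=0.0443
USA          OR=1.125 (0.912-1.388) p=0.271
pooled       OR=1.172 (1.067-1.287) p=0.000905
Q=40.1 (df=49) p=0.81; Egger intercept=-0.0066 p=0.61
power OR=1.2, r2=0.05: 0.838
```

Each cohort row is that cohort's IVW odds ratio per exposure s.d. with
its 95% CI; the pooled row is the fixed-effects meta-analysis across
cohorts (here correctly recovering exp(0.15) ≈ 1.162 within its CI).
The Q and Egger-intercept P-values show no evidence of heterogeneity or
directional pleiotropy, as expected for data generated without either.
The last line is the closed-form probability of detecting OR = 1.2 per
s.d. at α = 0.05 with instruments explaining 5% of exposure variance in
a study of this size.

The same analysis from the shell:

```sh
adipomr run-all --traits BMI,CHO --theta 0.15 --n-snps 50 --seed 42 --out-dir results/
```

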