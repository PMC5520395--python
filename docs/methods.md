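# Methods

## The analysis model

`adipomr` implements two-sample Mendelian randomisation (MR) at the
summary-statistic level.  For instrument SNP *j*, let β<sub>Xj</sub> be
the per-allele association with the exposure (in trait s.d. units, from
an exposure GWAS) and β<sub>Yj</sub> the per-allele association with the
outcome (log odds ratio for disease risk, log hazard ratio for
survival), with standard error σ<sub>Yj</sub>.  Under the instrumental
variable assumptions each Wald ratio β<sub>Yj</sub>/β<sub>Xj</sub>
estimates the causal effect θ of one exposure s.d. on the outcome log
scale.  The fixed-effects inverse-variance-weighted (IVW) estimator
combines them:

    θ̂ = Σⱼ β_Xj β_Yj / σ_Yj²  ÷  Σⱼ β_Xj² / σ_Yj²
    se(θ̂) = ( Σⱼ β_Xj² / σ_Yj² )^(−1/2)

equivalently the weighted least-squares slope of β<sub>Y</sub> on
β<sub>X</sub> through the origin with weights 1/σ<sub>Y</sub>².  Under
standard conditions this equals the two-stage estimate one would obtain
from an individual-level genetic risk score, which is why a GRS analysis
can be reproduced from summary statistics alone.  P-values use the
standard normal reference; 95% CIs use the multiplier 1.959964 on the
log scale and are exponentiated to the OR/HR scale.

Per-SNP Wald-ratio standard errors are first-order, σ<sub>Yj</sub>/|β<sub>Xj</sub>|,
ignoring exposure-side sampling error — the usual summary-data (NOME)
convention when instruments come from a much larger GWAS than the
outcome sample.  A second-order delta-method SE including
se(β<sub>X</sub>) is available behind a flag on `wald_ratio`.

Per-cohort estimates are pooled across outcome cohorts with the same
fixed-effects formula applied to the cohort log-ORs; between-cohort
Cochran's Q and I² = max(0, (Q − df)/Q) are reported descriptively.
Cohorts retaining zero instruments after harmonisation are excluded from
the pool and counted — expected behaviour when an instrument set is
absent from some outcome GWASs, not an error.

## Pleiotropy diagnostics

Two complementary tests probe the exclusion restriction:

* **Cochran's Q (IVW heterogeneity).**  Q = Σⱼ wⱼ (ratioⱼ − θ̂)² with
  wⱼ = β<sub>Xj</sub>²/σ<sub>Yj</sub>², referred to χ² on J − 1 df.
* **MR-Egger regression.**  Weighted regression of β<sub>Y</sub> on
  β<sub>X</sub> with a free intercept, after orienting every pair so
  β<sub>X</sub> ≥ 0.  The intercept estimates the average directional
  (horizontal) pleiotropic effect per SNP; the slope is a causal
  estimate that remains consistent under the InSIDE condition
  (direct effects independent of instrument strength).  Coefficient
  standard errors use a multiplicative residual dispersion floored at 1,
  and tests use t on J − 2 df — so the intercept test keeps its level
  in the presence of modest over-dispersion.

Where the analysis spans several cohorts, the trait-level tests run on
per-SNP associations first pooled across cohorts by fixed effects (the
`pooled` pseudo-cohort).  This yields one Q P-value and one Egger
P-value per trait — the natural trait-wise pair — and uses all cohorts'
information about each SNP.  Headline causal estimates, by contrast,
pool at the cohort level, matching the per-cohort forest-plot layout.

## Harmonisation

The exposure orientation is canonical: outcome records are flipped to
the exposure's effect allele, never vice versa, keeping instrument signs
stable across cohorts.  Non-palindromic pairs are resolved exactly
(allele swap ⇒ sign flip; strand complement ⇒ no sign change; both ⇒
sign flip); alleles that match under no representation are dropped as
incompatible with a warning.  Palindromic SNPs (A/T, C/G) are retained
only when both effect-allele frequencies are present, lie on the same
side of 0.5, and both fall outside the ambiguity band
[limit, 1 − limit] with limit defaulting to 0.42 (configurable); a
missing frequency on either side always drops the SNP.  Every
(instrument, cohort) combination appears in the output exactly once with
an explicit action, so exclusions are auditable and counts partition the
input.  Harmonisation is idempotent, and swapping an outcome file's
allele order with beta negation leaves all retained pairs bit-identical.

## Power

For a binary outcome with n = n_cases + n_controls, case fraction φ and
instrument variance explained r², the IVW log-OR estimate has asymptotic
standard error 1/√(n r² φ(1 − φ)), giving two-sided power

    power = Φ( |log OR| · √(n r² φ(1−φ)) − z_{1−α/2} )

Power is symmetric in OR ↔ 1/OR and equals α/2 at the null.  The r² of
a real instrument set is an input the user must supply (it is rarely
printed alongside published MR results); `power_curve` evaluates a grid.
The formula is validated by simulation: at a mid-power scenario
(6 839/22 221, J = 50, OR = 1.1/s.d.) the empirical IVW rejection rate
over 2 000 replicate outcome GWAS matches the closed form to well within
3 percentage points (the reproduction script recomputes this).

## Synthetic-data generator

The generator works at the summary level — the level the pipeline
consumes — so the MR assumptions appear directly as parameters:

* **Instruments.**  β<sub>Xj</sub> drawn from N(0.08, 0.025²) s.d. per
  allele with exposure SE 0.005, redrawn until |β̂/se| > 5.45
  (≈ P < 5×10⁻⁸), emulating strong anthropometric-trait instruments
  from a large exposure GWAS selected at genome-wide significance.  The
  significance truncation leaves winner's-curse inflation in the emitted
  effects deliberately (verified against a truncated-normal Monte-Carlo
  oracle); no debiasing is applied.  EAF ~ U(0.05, 0.95); allele pairs
  avoid palindromes unless requested.
* **Outcomes.**  β<sub>Yj,c</sub> ~ N(θ·β<sub>Xj</sub> + α<sub>j</sub>,
  σ<sub>Yc</sub>²) per cohort, conditioning on the emitted instrument
  effects.  Conditioning on the published effects (rather than latent
  true effects) makes the first-order estimators' no-measurement-error
  convention exact, so bias and coverage checks isolate the estimator's
  own properties; the cost is that exposure-side regression dilution is
  not part of the generated data, and tests passing here do not speak to
  weak-instrument settings.
* **Cohorts.**  σ<sub>Yc</sub> = c/√(n_cases·n_controls/n_total) with
  calibration constant c = 2.0, the per-allele log-OR SE of a variant
  with 2p(1−p) = 0.25.  The default design is five cohorts (UK, Germany,
  Netherlands, Sweden, USA) splitting 6 839 cases and 22 221 controls
  evenly; per-cohort case/control splits are configurable since real
  per-cohort totals vary.  Per-cohort instrument dropout is independent
  Bernoulli(1 − retention), allowing whole-cohort instrument absence
  (retention 0).
* **Pleiotropy.**  α<sub>j</sub> = 0 (`none`); N(0, σ_α²) with default
  σ_α = 0.003 (`balanced` — direct effects an order of magnitude below
  the outcome sampling SE ≈ 0.028, the regime in which both pleiotropy
  tests should hold their level); N(μ_α, σ_α²) (`directional`,
  satisfying InSIDE since α is independent of β<sub>X</sub>).  With
  `inside_violation` the direct effect is instead a deterministic linear
  function of instrument strength, μ_α + σ_α·(β<sub>X</sub> − mean)/sd,
  the worst case for the Egger slope.

What the generator does **not** emulate: LD between instruments,
exposure/outcome sample overlap, weak instruments (mean instrument
z ≈ 16), allele-frequency differences between studies, mis-specified
variant identifiers, or genuinely binary-trait likelihoods (outcome
effects are Gaussian around their mean, the asymptotic regime).  Results
on real data with weak or correlated instruments can differ.

## Numerical and design choices

* IVW with a single instrument returns the Wald ratio bit-exactly
  (special-cased rather than evaluated as a one-term sum).
* β<sub>X</sub> = 0 after harmonisation raises an error naming the SNP —
  it indicates an invalid instrument file, and is never silently dropped.
* MR-Egger requires ≥ 3 instruments and raises a collinearity error if
  all oriented β<sub>X</sub> are identical.
* Reported p-values are floored at 1e-300 to stay in (0, 1].
* Floats are serialised with 17 significant digits, so every
  table write/read round-trips losslessly.
* All randomness flows from `numpy.random.SeedSequence` spawned per
  stream (instruments vs outcomes vs replicates), making every generator
  and pipeline run fully deterministic given its seed, and replicate
  streams independent.
* No multiplicity adjustment is applied to the per-trait P-values (the
  analysis reports unadjusted two-sided tests); a Bonferroni column
  across the analysed traits is emitted alongside for transparency.

## Replicate experiment sizes

The packaged operating-characteristic experiments (`adipomr.calibration`,
also run by `scripts/acceptance.py`) use 1 000 replicate studies for
recovery/coverage, type-I error and bias separation, and 2 000 for power
calibration, with J = 50 instruments — sizes at which Monte-Carlo error
is a few thousandths on a mean estimate and under ±1 percentage point
on a rejection rate, while a full run stays in the tens of seconds.

## Known limitations

* No weighted-median / mode-based / multivariable MR estimators.
* No LD-proxy lookup or clumping; instruments are assumed independent
  index SNPs matched by identifier string.
* Fixed-effects pooling only for the headline estimate (random-effects
  pooling is not implemented); heterogeneity is surfaced via Q and I².
* The power formula covers binary outcomes only; survival analyses
  reuse the same estimator arithmetic but no HR power calculation is
  provided.
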