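"""Simulation-based operating characteristics of the MR estimators.

These experiments run the real pipeline path — synthetic summary
statistics, harmonisation, estimation, pooling — over many replicate
studies and summarise bias, confidence-interval coverage, type-I error
of the pleiotropy tests, and the agreement between the closed-form power
approximation and the empirical rejection rate.  They are what the test
suite and the reproduction script rely on, and are useful on their own
for study planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimators import cochran_q, ivw_fixed_effects, mr_egger
from .harmonization import harmonize
from .meta_analysis import meta_fixed
from .pipeline import pool_pairs_across_cohorts
from .power import mr_power
from .records import Z95, PowerScenario
from .synthetic import CohortSpec, SimulationTruth, simulate_instruments, simulate_outcomes


def _replicate_seeds(seed: int, n_reps: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_reps)


def _one_study(truth: SimulationTruth, ss: np.random.SeedSequence):
    """One replicate through the full summary-data path."""
    child_a, child_b = ss.spawn(2)
    instruments = simulate_instruments(truth, rng=np.random.default_rng(child_a))
    outcomes = simulate_outcomes(truth, instruments, rng=np.random.default_rng(child_b))
    flat = [rec for cohort in outcomes.values() for rec in cohort]
    return harmonize(instruments, flat)


@dataclass(frozen=True)
class RecoveryResult:
    """Bias and coverage of the pooled IVW estimate over replicates."""

    mean_estimate: float
    mc_se: float
    coverage: float
    theta: float
    n_reps: int

    @property
    def bias(self) -> float:
        return self.mean_estimate - self.theta

    @property
    def within_3_mc_se(self) -> bool:
        return abs(self.bias) <= 3.0 * self.mc_se


def ivw_recovery(truth: SimulationTruth, n_reps: int, seed: int) -> RecoveryResult:
    """Replicate the study design and pool per-cohort IVW estimates.

    Reports the mean pooled estimate, its Monte-Carlo standard error and
    the empirical coverage of the pooled 95% CI for the generating theta.
    """
    estimates = np.empty(n_reps)
    covered = 0
    for i, ss in enumerate(_replicate_seeds(seed, n_reps)):
        pairs = _one_study(truth, ss)
        by_cohort: dict[str, list] = {}
        for p in pairs:
            by_cohort.setdefault(p.cohort, []).append(p)
        cohort_estimates = [
            ivw_fixed_effects(cp)
            for cp in by_cohort.values()
            if any(p.retained for p in cp)
        ]
        meta = meta_fixed(cohort_estimates)
        estimates[i] = meta.beta_pooled
        lo = meta.beta_pooled - Z95 * meta.se_pooled
        hi = meta.beta_pooled + Z95 * meta.se_pooled
        covered += lo <= truth.theta <= hi
    return RecoveryResult(
        mean_estimate=float(estimates.mean()),
        mc_se=float(estimates.std(ddof=1) / math.sqrt(n_reps)),
        coverage=covered / n_reps,
        theta=truth.theta,
        n_reps=n_reps,
    )


@dataclass(frozen=True)
class Type1Result:
    """Rejection rates of the pleiotropy tests at the given alpha."""

    egger_intercept_rate: float
    cochran_q_rate: float
    alpha: float
    n_reps: int


def pleiotropy_type1(
    truth: SimulationTruth, n_reps: int, seed: int, alpha: float = 0.05
) -> Type1Result:
    """Type-I error of the Egger intercept test and Cochran's Q.

    Intended for null regimes: theta arbitrary, pleiotropy balanced (the
    intercept truly zero) with direct effects small against the outcome
    sampling error, so neither test should fire beyond its level.
    """
    egger_rej = 0
    q_rej = 0
    for ss in _replicate_seeds(seed, n_reps):
        pairs = _one_study(truth, ss)
        pooled = pool_pairs_across_cohorts(pairs)
        ivw = ivw_fixed_effects(pooled)
        egger_rej += mr_egger(pooled).p_intercept < alpha
        q_rej += cochran_q(pooled, ivw).p_het < alpha
    return Type1Result(
        egger_intercept_rate=egger_rej / n_reps,
        cochran_q_rate=q_rej / n_reps,
        alpha=alpha,
        n_reps=n_reps,
    )


@dataclass(frozen=True)
class BiasSeparationResult:
    """IVW versus Egger under directional pleiotropy satisfying InSIDE."""

    ivw_mean: float
    egger_slope_mean: float
    egger_intercept_mean: float
    egger_intercept_mc_se: float
    theta: float
    mu_alpha: float
    n_reps: int

    @property
    def ivw_bias(self) -> float:
        return self.ivw_mean - self.theta

    @property
    def egger_slope_bias(self) -> float:
        return self.egger_slope_mean - self.theta


def bias_separation(truth: SimulationTruth, n_reps: int, seed: int) -> BiasSeparationResult:
    """Quantify how directional pleiotropy biases IVW but not the Egger slope.

    Under InSIDE the Egger intercept should recover the mean direct
    effect mu_alpha while the IVW estimate absorbs it into the slope.
    """
    ivw_vals = np.empty(n_reps)
    slope_vals = np.empty(n_reps)
    intercept_vals = np.empty(n_reps)
    for i, ss in enumerate(_replicate_seeds(seed, n_reps)):
        pairs = _one_study(truth, ss)
        pooled = pool_pairs_across_cohorts(pairs)
        ivw_vals[i] = ivw_fixed_effects(pooled).beta_hat
        egger = mr_egger(pooled)
        slope_vals[i] = egger.slope
        intercept_vals[i] = egger.intercept
    return BiasSeparationResult(
        ivw_mean=float(ivw_vals.mean()),
        egger_slope_mean=float(slope_vals.mean()),
        egger_intercept_mean=float(intercept_vals.mean()),
        egger_intercept_mc_se=float(intercept_vals.std(ddof=1) / math.sqrt(n_reps)),
        theta=truth.theta,
        mu_alpha=truth.mu_alpha,
        n_reps=n_reps,
    )


@dataclass(frozen=True)
class PowerCalibrationResult:
    """Closed-form power prediction versus empirical rejection rate."""

    predicted: float
    empirical: float
    r_squared: float
    scenario: PowerScenario
    n_reps: int

    @property
    def abs_difference(self) -> float:
        return abs(self.predicted - self.empirical)


def power_calibration(
    theta: float,
    n_reps: int,
    seed: int,
    n_cases: int = 6839,
    n_controls: int = 22221,
    n_snps: int = 50,
    alpha: float = 0.05,
) -> PowerCalibrationResult:
    """Check the closed-form power formula against simulation.

    One instrument set is drawn and held fixed; ``n_reps`` outcome GWAS
    of the stated size are simulated at causal effect ``theta`` and
    tested with IVW at level ``alpha``.  The formula's r^2 input is the
    instruments' effective variance explained implied by the generator's
    standard-error calibration, ``sum(beta_x^2) / c^2``, so prediction
    and simulation describe the same instrument strength.
    """
    cohort = CohortSpec(name="ALL", n_cases=n_cases, n_controls=n_controls)
    truth = SimulationTruth(theta=theta, n_snps=n_snps, cohorts=(cohort,), seed=seed)
    root = np.random.SeedSequence(seed)
    inst_ss, *rep_ss = root.spawn(n_reps + 1)
    instruments = simulate_instruments(truth, rng=np.random.default_rng(inst_ss))
    bx2 = sum(r.beta_exposure**2 for r in instruments)
    r_squared = bx2 / truth.se_y_scale**2
    rejected = 0
    for ss in rep_ss:
        outcomes = simulate_outcomes(truth, instruments, rng=np.random.default_rng(ss))
        pairs = harmonize(instruments, outcomes[cohort.name])
        rejected += ivw_fixed_effects(pairs).pvalue < alpha
    scenario = PowerScenario(
        n_cases=n_cases,
        n_controls=n_controls,
        r_squared=r_squared,
        or_per_sd=math.exp(theta),
        alpha=alpha,
    )
    return PowerCalibrationResult(
        predicted=mr_power(scenario),
        empirical=rejected / n_reps,
        r_squared=r_squared,
        scenario=scenario,
        n_reps=n_reps,
    )


def balanced_null_truth(
    n_snps: int = 50,
    sigma_alpha: float = 0.003,
    seed: int = 0,
) -> SimulationTruth:
    """Null study (theta = 0) with weak balanced pleiotropy on a single
    full-size outcome GWAS — the standard regime for checking that the
    pleiotropy tests hold their level."""
    cohort = CohortSpec(name="ALL", n_cases=6839, n_controls=22221)
    return SimulationTruth(
        theta=0.0,
        n_snps=n_snps,
        cohorts=(cohort,),
        pleiotropy="balanced",
        mu_alpha=0.0,
        sigma_alpha=sigma_alpha,
        seed=seed,
    )


def directional_truth(
    theta: float = 0.0,
    mu_alpha: float = 0.02,
    sigma_alpha: float = 0.01,
    n_snps: int = 50,
    seed: int = 0,
) -> SimulationTruth:
    """Directional-pleiotropy study satisfying InSIDE (independent direct
    effects with non-zero mean), on a single full-size outcome GWAS."""
    cohort = CohortSpec(name="ALL", n_cases=6839, n_controls=22221)
    return SimulationTruth(
        theta=theta,
        n_snps=n_snps,
        cohorts=(cohort,),
        pleiotropy="directional",
        mu_alpha=mu_alpha,
        sigma_alpha=sigma_alpha,
        seed=seed,
    )
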