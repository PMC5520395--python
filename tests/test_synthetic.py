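import math

import numpy as np
import pytest

from adipomr.estimators import ivw_fixed_effects, mr_egger
from adipomr.exceptions import SimulationError
from adipomr.harmonization import harmonize
from adipomr.pipeline import pool_pairs_across_cohorts
from adipomr.synthetic import (
    CohortSpec,
    SimulationTruth,
    default_cohorts,
    read_truth,
    scramble_alleles,
    simulate_instruments,
    simulate_study,
    write_truth,
)


def small_truth(**kw):
    base = dict(theta=0.1, n_snps=12, seed=3)
    base.update(kw)
    return SimulationTruth(**base)


class TestSimulateInstruments:
    def test_fixed_seed_is_fully_deterministic(self):
        a = simulate_instruments(small_truth())
        b = simulate_instruments(small_truth())
        assert a == b

    def test_all_records_clear_the_significance_threshold(self):
        truth = small_truth(n_snps=200)
        for rec in simulate_instruments(truth):
            assert abs(rec.beta_exposure) / rec.se_exposure > truth.gw_z_threshold

    def test_truncated_mean_matches_monte_carlo_oracle(self):
        """The emitted effects follow a normal truncated on the published
        estimate clearing |z| > threshold; an independent direct Monte-Carlo
        sampler of that truncated distribution gives the expected mean."""
        truth = SimulationTruth(theta=0.0, n_snps=10_000, beta_x_mean=0.03,
                                beta_x_sd=0.01, se_x=0.006, seed=5)
        emitted = np.array([r.beta_exposure for r in simulate_instruments(truth)])
        oracle_rng = np.random.default_rng(12345)
        marg_sd = math.sqrt(truth.beta_x_sd**2 + truth.se_x**2)
        draws = oracle_rng.normal(truth.beta_x_mean, marg_sd, 2_000_000)
        accepted = draws[np.abs(draws) / truth.se_x > truth.gw_z_threshold]
        se_mean = accepted.std() / math.sqrt(len(emitted))
        assert abs(emitted.mean() - accepted.mean()) < 3 * se_mean
        # truncation induces winner's curse: mean exceeds the generating mean
        assert emitted.mean() > truth.beta_x_mean

    def test_unreachable_threshold_raises(self):
        truth = small_truth(beta_x_mean=0.0, beta_x_sd=1e-6, se_x=1.0, gw_z_threshold=8.0)
        with pytest.raises(SimulationError):
            simulate_instruments(truth)

    def test_non_palindromic_alleles_by_default(self):
        complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for rec in simulate_instruments(small_truth(n_snps=100)):
            assert complement[rec.effect_allele] != rec.other_allele


class TestSimulateOutcomes:
    def test_zero_retention_cohort_emits_no_records(self):
        cohorts = tuple(default_cohorts()[:3]) + (
            CohortSpec("UK2", 1000, 3000, retention=0.0),
        )
        truth = small_truth(cohorts=cohorts)
        study = simulate_study(truth)
        assert study.outcomes["UK2"] == []
        assert len(study.outcomes[cohorts[0].name]) > 0

    def test_se_reflects_cohort_composition(self):
        truth = small_truth()
        study = simulate_study(truth)
        for cohort in truth.cohorts:
            expected = truth.se_y_scale / math.sqrt(cohort.effective_n)
            assert all(r.se_outcome == expected for r in study.outcomes[cohort.name])

    def test_null_theta_recovers_zero_on_average(self):
        """Parameter recovery at theta = 0: the mean IVW estimate over
        replicates is centred on zero."""
        n_reps = 300
        estimates = np.empty(n_reps)
        cohort = CohortSpec("ALL", 3000, 9000)
        for r in range(n_reps):
            truth = SimulationTruth(theta=0.0, n_snps=20, cohorts=(cohort,), seed=r)
            study = simulate_study(truth)
            pairs = harmonize(study.instruments, study.all_outcomes)
            estimates[r] = ivw_fixed_effects(pairs).beta_hat
        mc_se = estimates.std(ddof=1) / math.sqrt(n_reps)
        assert abs(estimates.mean()) < 3 * mc_se

    def test_directional_pleiotropy_mean_shows_up_in_egger_intercept(self):
        n_reps = 200
        intercepts = np.empty(n_reps)
        cohort = CohortSpec("ALL", 6839, 22221)
        for r in range(n_reps):
            truth = SimulationTruth(
                theta=0.0, n_snps=30, cohorts=(cohort,), pleiotropy="directional",
                mu_alpha=0.03, sigma_alpha=0.01, seed=10_000 + r,
            )
            study = simulate_study(truth)
            pairs = harmonize(study.instruments, study.all_outcomes)
            intercepts[r] = mr_egger(pairs).intercept
        mc_se = intercepts.std(ddof=1) / math.sqrt(n_reps)
        assert abs(intercepts.mean() - 0.03) < 3 * mc_se

    def test_inside_violation_couples_alpha_to_instrument_strength(self):
        truth = small_truth(
            n_snps=40, pleiotropy="directional", mu_alpha=0.05, sigma_alpha=0.02,
            inside_violation=True, theta=0.0,
            cohorts=(CohortSpec("ALL", 10**6, 3 * 10**6),),  # tiny outcome noise
        )
        study = simulate_study(truth)
        bx = np.array([r.beta_exposure for r in study.instruments])
        by = np.array([r.beta_outcome for r in study.outcomes["ALL"]])
        # with theta=0 the outcome effect is essentially alpha_j
        assert np.corrcoef(bx, by)[0, 1] > 0.9


class TestScrambleAlleles:
    def test_fraction_zero_is_identity(self):
        study = simulate_study(small_truth())
        records = study.outcomes[study.truth.cohorts[0].name]
        assert scramble_alleles(records, 0.0, seed=1) == records

    def test_fixed_seed_is_deterministic(self):
        study = simulate_study(small_truth())
        records = study.all_outcomes
        assert scramble_alleles(records, 0.7, seed=9) == scramble_alleles(records, 0.7, seed=9)

    def test_full_scramble_round_trips_through_harmonizer(self):
        study = simulate_study(small_truth(n_snps=30))
        original = harmonize(study.instruments, study.all_outcomes)
        scrambled = scramble_alleles(study.all_outcomes, 1.0, seed=11)
        recovered = harmonize(study.instruments, scrambled)
        assert len(original) == len(recovered)
        for a, b in zip(original, recovered):
            assert a.snp_id == b.snp_id and a.cohort == b.cohort
            assert a.retained and b.retained
            assert a.beta_y == b.beta_y
            assert a.se_y == b.se_y

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            scramble_alleles([], 1.5, seed=0)


class TestTruthSerialization:
    def test_truth_round_trips_through_json(self, tmp_path):
        truth = small_truth(pleiotropy="directional", mu_alpha=0.02, sigma_alpha=0.01)
        write_truth(truth, tmp_path / "truth.json")
        assert read_truth(tmp_path / "truth.json") == truth

    def test_balanced_regime_requires_zero_mean(self):
        with pytest.raises(ValueError):
            small_truth(pleiotropy="balanced", mu_alpha=0.01)

    def test_retention_bounds_enforced(self):
        with pytest.raises(ValueError):
            CohortSpec("x", 10, 10, retention=1.2)


def test_study_generation_is_deterministic_end_to_end():
    t = small_truth(seed=77)
    s1, s2 = simulate_study(t), simulate_study(t)
    assert s1.instruments == s2.instruments
    assert s1.outcomes == s2.outcomes


def test_pooling_across_cohorts_shrinks_se():
    study = simulate_study(small_truth())
    pairs = harmonize(study.instruments, study.all_outcomes)
    pooled = pool_pairs_across_cohorts(pairs)
    assert len(pooled) == study.truth.n_snps
    per_cohort_min_se = min(p.se_y for p in pairs if p.retained)
    assert all(p.se_y <= per_cohort_min_se for p in pooled)
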