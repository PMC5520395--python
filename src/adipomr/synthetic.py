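"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly at the summary level, which is the level
the whole pipeline consumes.  For each of ``J`` instruments it draws a
published exposure effect (in trait s.d. units) from a normal
distribution, re-drawing until the estimate clears a genome-wide
significance z-threshold — the instrument-selection rule used for real
GWAS-significant index SNPs, which leaves the familiar winner's-curse
truncation in the emitted effects.  Outcome associations are then drawn
per cohort as

    beta_outcome ~ Normal(theta * beta_exposure + alpha_j, se_y^2)

where ``theta`` is the true causal effect (log-OR or log-HR per s.d.),
``alpha_j`` the SNP's direct (pleiotropic) effect on the outcome, and
``se_y = c / sqrt(n_cases * n_controls / n_total)`` reflects the
cohort's size.  Pleiotropy regimes: ``none`` (alpha_j = 0), ``balanced``
(zero-mean alpha_j), ``directional`` (non-zero mean).  Setting
``inside_violation`` couples alpha_j deterministically to instrument
strength, breaking the InSIDE condition that MR-Egger relies on.
Per-cohort instrument dropout (each SNP independently missing with
probability 1 - retention) emulates whole-cohort instrument loss.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import SimulationError
from .records import InstrumentRecord, OutcomeRecord, OutcomeScale

#: z-threshold equivalent to the genome-wide significance level P < 5e-8.
GENOME_WIDE_Z = 5.45

#: Ordered non-palindromic allele pairs the generator samples from.
_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class CohortSpec:
    """One outcome cohort: sample composition and instrument retention."""

    name: str
    n_cases: int
    n_controls: int
    retention: float = 1.0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(f"{self.name}: case/control counts must be positive")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError(f"{self.name}: retention must be in [0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def effective_n(self) -> float:
        """n_cases * n_controls / n_total, the binary-trait effective size."""
        return self.n_cases * self.n_controls / self.n_total


def default_cohorts(retention: float = 1.0) -> list[CohortSpec]:
    """Five cohorts splitting 6 839 cases and 22 221 controls evenly."""
    cases = [1368, 1368, 1368, 1368, 1367]
    controls = [4445, 4444, 4444, 4444, 4444]
    names = ["UK", "Germany", "Netherlands", "Sweden", "USA"]
    return [
        CohortSpec(name=n, n_cases=a, n_controls=b, retention=retention)
        for n, a, b in zip(names, cases, controls)
    ]


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of one synthetic two-sample MR study.

    ``theta`` is the true causal effect per exposure s.d. on the outcome
    log scale.  ``beta_x_mean``/``beta_x_sd`` describe the instrument
    effect distribution before significance truncation and ``se_x`` the
    exposure GWAS standard error (defaults emulate instruments from a
    large exposure GWAS: mean 0.08 s.d./allele, SE 0.005, so mean
    z ~ 16).  ``se_y_scale`` is the calibration constant c in
    ``se_y = c / sqrt(effective n)``; the default 2.0 corresponds to a
    per-allele log-OR SE for a variant with 2*p*(1-p) = 0.25.
    """

    theta: float
    n_snps: int = 50
    beta_x_mean: float = 0.08
    beta_x_sd: float = 0.025
    se_x: float = 0.005
    cohorts: tuple[CohortSpec, ...] = field(default_factory=lambda: tuple(default_cohorts()))
    pleiotropy: str = "none"
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.003
    inside_violation: bool = False
    seed: int = 0
    outcome_scale: OutcomeScale = OutcomeScale.LOG_ODDS
    gw_z_threshold: float = GENOME_WIDE_Z
    se_y_scale: float = 2.0
    allow_palindromic: bool = False

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy not in {"none", "balanced", "directional"}:
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.pleiotropy == "balanced" and self.mu_alpha != 0.0:
            raise ValueError("balanced pleiotropy requires mu_alpha = 0")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be >= 0")
        if self.se_x <= 0 or self.beta_x_sd < 0:
            raise ValueError("se_x must be > 0 and beta_x_sd >= 0")
        object.__setattr__(self, "cohorts", tuple(self.cohorts))

    def cohort_se_y(self, cohort: CohortSpec) -> float:
        return self.se_y_scale / math.sqrt(cohort.effective_n)


def _rng_for(truth: SimulationTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(stream + 1)[stream])


_MAX_DRAWS_PER_SNP = 100_000


def simulate_instruments(
    truth: SimulationTruth,
    trait: str = "SIM",
    rng: np.random.Generator | None = None,
) -> list[InstrumentRecord]:
    """Draw ``truth.n_snps`` genome-wide-significant instrument records.

    Each SNP's (true effect, estimate) pair is redrawn until
    ``|beta/se| > gw_z_threshold``, so emitted effects follow the
    significance-truncated distribution real instrument lists exhibit.
    """
    if rng is None:
        rng = _rng_for(truth, 0)
    allele_pairs = (
        _NON_PALINDROMIC_PAIRS + _PALINDROMIC_PAIRS
        if truth.allow_palindromic
        else _NON_PALINDROMIC_PAIRS
    )
    records: list[InstrumentRecord] = []
    for j in range(truth.n_snps):
        for _ in range(_MAX_DRAWS_PER_SNP):
            true_beta = rng.normal(truth.beta_x_mean, truth.beta_x_sd)
            beta_hat = true_beta + rng.normal(0.0, truth.se_x)
            if abs(beta_hat) / truth.se_x > truth.gw_z_threshold:
                break
        else:
            raise SimulationError(
                f"could not reach |z| > {truth.gw_z_threshold} after "
                f"{_MAX_DRAWS_PER_SNP} draws; threshold unreachable for these parameters"
            )
        eaf = float(rng.uniform(0.05, 0.95))
        ea, oa = allele_pairs[int(rng.integers(len(allele_pairs)))]
        p = float(max(2.0 * stats.norm.sf(abs(beta_hat) / truth.se_x), 1e-300))
        records.append(
            InstrumentRecord(
                snp_id=f"snp{j:04d}",
                effect_allele=ea,
                other_allele=oa,
                beta_exposure=float(beta_hat),
                se_exposure=truth.se_x,
                eaf=eaf,
                pvalue_exposure=p,
                trait=trait,
            )
        )
    return records


def _pleiotropy_effects(
    truth: SimulationTruth, bx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if truth.pleiotropy == "none":
        return np.zeros_like(bx)
    if truth.inside_violation:
        # Deterministic coupling of direct effects to instrument strength.
        sd = bx.std() if bx.std() > 0 else 1.0
        return truth.mu_alpha + truth.sigma_alpha * (bx - bx.mean()) / sd
    return rng.normal(truth.mu_alpha, truth.sigma_alpha, size=bx.size)


def simulate_outcomes(
    truth: SimulationTruth,
    instruments: list[InstrumentRecord],
    rng: np.random.Generator | None = None,
) -> dict[str, list[OutcomeRecord]]:
    """Draw per-cohort outcome associations for the given instruments.

    The generative model conditions on the emitted instrument effects
    (``beta_exposure`` of the records plays the role of the true
    SNP-exposure effect), so the simulated study satisfies the NO
    Measurement Error convention of the summary-data estimators.  Each
    SNP's pleiotropic effect alpha_j is drawn once and shared across
    cohorts; instrument dropout is independent per (SNP, cohort).
    """
    if rng is None:
        rng = _rng_for(truth, 1)
    bx = np.array([r.beta_exposure for r in instruments], dtype=float)
    alpha = _pleiotropy_effects(truth, bx, rng)
    means = truth.theta * bx + alpha
    out: dict[str, list[OutcomeRecord]] = {}
    for cohort in truth.cohorts:
        se_y = truth.cohort_se_y(cohort)
        keep = rng.random(bx.size) < cohort.retention
        betas = rng.normal(means, se_y)
        records = [
            OutcomeRecord(
                snp_id=inst.snp_id,
                effect_allele=inst.effect_allele,
                other_allele=inst.other_allele,
                beta_outcome=float(betas[j]),
                se_outcome=se_y,
                eaf=inst.eaf,
                cohort=cohort.name,
                outcome_scale=truth.outcome_scale,
            )
            for j, inst in enumerate(instruments)
            if keep[j]
        ]
        out[cohort.name] = records
    return out


@dataclass(frozen=True)
class SimulatedStudy:
    """A complete synthetic study: truth, instruments, per-cohort outcomes."""

    truth: SimulationTruth
    instruments: list[InstrumentRecord]
    outcomes: dict[str, list[OutcomeRecord]]

    @property
    def all_outcomes(self) -> list[OutcomeRecord]:
        return [rec for cohort in self.outcomes.values() for rec in cohort]


def simulate_study(truth: SimulationTruth, trait: str = "SIM") -> SimulatedStudy:
    """Generate instruments and outcomes from one seed, deterministically."""
    instruments = simulate_instruments(truth, trait=trait, rng=_rng_for(truth, 0))
    outcomes = simulate_outcomes(truth, instruments, rng=_rng_for(truth, 1))
    return SimulatedStudy(truth=truth, instruments=instruments, outcomes=outcomes)


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def scramble_alleles(
    outcomes: list[OutcomeRecord],
    fraction: float,
    seed: int,
    order_swap: bool = True,
    strand_flip: bool = True,
) -> list[OutcomeRecord]:
    """Perturb allele representation without changing the harmonised truth.

    A random ``fraction`` of records get an allele-order swap (with beta
    negation and EAF complementation) and/or a strand complement.  Strand
    complements are only applied to non-palindromic records, where the
    harmonizer can resolve them deterministically.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not (order_swap or strand_flip):
        return list(outcomes)
    rng = np.random.default_rng(seed)
    result: list[OutcomeRecord] = []
    for rec in outcomes:
        if rng.random() >= fraction:
            result.append(rec)
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        beta, eaf = rec.beta_outcome, rec.eaf
        palindromic = _COMPLEMENT[ea] == oa
        ops = []
        if order_swap:
            ops.append("swap")
        if strand_flip and not palindromic:
            ops.append("strand")
            if order_swap:
                ops.append("both")
        if not ops:
            result.append(rec)
            continue
        op = ops[int(rng.integers(len(ops)))]
        do_swap = op in ("swap", "both")
        do_strand = op in ("strand", "both")
        if do_swap:
            ea, oa = oa, ea
            beta = -beta
            eaf = None if eaf is None else 1.0 - eaf
        if do_strand:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        result.append(
            OutcomeRecord(
                snp_id=rec.snp_id,
                effect_allele=ea,
                other_allele=oa,
                beta_outcome=beta,
                se_outcome=rec.se_outcome,
                eaf=eaf,
                cohort=rec.cohort,
                outcome_scale=rec.outcome_scale,
            )
        )
    return result


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Record the generating parameters as JSON for test harnesses."""
    payload = dataclasses.asdict(truth)
    payload["outcome_scale"] = truth.outcome_scale.value
    payload["cohorts"] = [dataclasses.asdict(c) for c in truth.cohorts]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    payload["cohorts"] = tuple(CohortSpec(**c) for c in payload["cohorts"])
    payload["outcome_scale"] = OutcomeScale(payload["outcome_scale"])
    return SimulationTruth(**payload)
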