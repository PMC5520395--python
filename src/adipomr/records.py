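"""Core domain types for summary-statistic Mendelian randomisation.

All effect sizes live on additive scales: exposure effects in standard
deviations of the trait per effect allele, outcome effects as per-allele
log odds ratios (binary outcomes) or log hazard ratios (survival
outcomes).  Ratio-scale quantities (OR/HR) are derived views obtained by
exponentiation and are never stored as the primary value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

VALID_ALLELES = frozenset("ACGT")

#: Two-sided 95% normal quantile used for every confidence interval.
Z95 = 1.959964


class OutcomeScale(str, enum.Enum):
    """Scale of the outcome association: log odds ratio or log hazard ratio."""

    LOG_ODDS = "log_odds"
    LOG_HAZARD = "log_hazard"

    @property
    def ratio_label(self) -> str:
        return "OR" if self is OutcomeScale.LOG_ODDS else "HR"


class HarmonizationAction(str, enum.Enum):
    """What the harmonizer did to align an (exposure, outcome) SNP pair."""

    AS_IS = "as_is"
    SIGN_FLIPPED = "sign_flipped"
    STRAND_FLIPPED = "strand_flipped"
    STRAND_AND_SIGN_FLIPPED = "strand_and_sign_flipped"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_MISSING = "dropped_missing"
    DROPPED_INCOMPATIBLE = "dropped_incompatible"

    @property
    def retained(self) -> bool:
        return not self.value.startswith("dropped")


def _check_allele(allele: str, name: str) -> None:
    if allele not in VALID_ALLELES:
        raise ValueError(f"{name} must be one of A/C/G/T, got {allele!r}")


@dataclass(frozen=True)
class InstrumentRecord:
    """One SNP's association with the exposure trait.

    ``beta_exposure`` is the per-allele effect in s.d. units of the trait,
    as published by the exposure GWAS.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    trait: str
    eaf: float | None = None
    pvalue_exposure: float | None = None

    def __post_init__(self):
        _check_allele(self.effect_allele, "effect_allele")
        _check_allele(self.other_allele, "other_allele")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se_exposure > 0:
            raise ValueError(f"{self.snp_id}: se_exposure must be > 0")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: eaf must be in (0, 1)")
        if self.pvalue_exposure is not None and not 0 < self.pvalue_exposure <= 1:
            raise ValueError(f"{self.snp_id}: pvalue_exposure must be in (0, 1]")


@dataclass(frozen=True)
class OutcomeRecord:
    """One SNP's association with the outcome in one cohort."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_outcome: float
    se_outcome: float
    cohort: str
    outcome_scale: OutcomeScale = OutcomeScale.LOG_ODDS
    eaf: float | None = None

    def __post_init__(self):
        _check_allele(self.effect_allele, "effect_allele")
        _check_allele(self.other_allele, "other_allele")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se_outcome > 0:
            raise ValueError(f"{self.snp_id}: se_outcome must be > 0")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: eaf must be in (0, 1)")


@dataclass(frozen=True)
class HarmonizedPair:
    """An allele-aligned (exposure, outcome) effect pair for one SNP in one cohort.

    Both betas are oriented to the exposure's effect allele.  Dropped pairs
    keep their action label but carry NaN outcome fields so they cannot be
    used in estimation by accident.
    """

    snp_id: str
    cohort: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    action: HarmonizationAction
    trait: str = ""
    outcome_scale: OutcomeScale = OutcomeScale.LOG_ODDS

    @property
    def retained(self) -> bool:
        return self.action.retained


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the outcome log scale.

    ``beta_hat`` is the change in log-OR (or log-HR) per 1 s.d. increase in
    the exposure; ``ratio_scale`` is exp(beta_hat) reported as an OR or HR.
    """

    trait: str
    cohort: str
    method: str
    beta_hat: float
    se_hat: float
    ratio_scale: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    outcome_scale: OutcomeScale

    @property
    def weight(self) -> float:
        """Inverse-variance weight used in meta-analysis and forest plots."""
        return 1.0 / self.se_hat**2


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger weighted regression: slope (causal estimate) and intercept
    (average directional pleiotropy per SNP), with t-based tests on
    ``df = n_snps - 2`` degrees of freedom."""

    trait: str
    cohort: str
    slope: float
    se_slope: float
    intercept: float
    se_intercept: float
    p_slope: float
    p_intercept: float
    df: int
    n_snps: int


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios, chi-square on n_snps - 1 df."""

    trait: str
    cohort: str
    q_statistic: float
    df: int
    p_het: float
    n_snps: int


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects pooled causal estimate across cohorts for one trait."""

    trait: str
    beta_pooled: float
    se_pooled: float
    or_pooled: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_cohorts: int
    cochran_q_cohorts: float
    i_squared: float
    outcome_scale: OutcomeScale = OutcomeScale.LOG_ODDS


#: Label used for the pooled (diamond) row of a forest plot.
SUMMARY_LABEL = "summary"


@dataclass(frozen=True)
class ForestRow:
    """One line of a forest plot: a cohort box or the pooled summary diamond."""

    trait: str
    label: str
    estimate_or: float
    ci_low: float
    ci_high: float
    weight: float

    @property
    def is_summary(self) -> bool:
        return self.label == SUMMARY_LABEL


@dataclass(frozen=True)
class PowerScenario:
    """Inputs to the binary-outcome MR power approximation.

    ``r_squared`` is the proportion of exposure variance jointly explained
    by the instruments; ``or_per_sd`` is the postulated causal odds ratio
    per s.d. of exposure.
    """

    n_cases: int
    n_controls: int
    r_squared: float
    or_per_sd: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not 0 < self.r_squared < 1:
            raise ValueError("r_squared must be in (0, 1)")
        if not self.or_per_sd > 0:
            raise ValueError("or_per_sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total
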