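"""Summary-statistic MR estimators: Wald ratio, IVW, MR-Egger, Cochran's Q.

The inverse-variance-weighted (IVW) fixed-effects estimator combines the
per-SNP Wald ratios ``beta_y / beta_x`` with weights ``beta_x^2 / se_y^2``:

    beta_hat = sum_j(beta_xj * beta_yj / se_yj^2) / sum_j(beta_xj^2 / se_yj^2)
    se_hat   = sqrt(1 / sum_j(beta_xj^2 / se_yj^2))

which is algebraically the weighted-least-squares slope of ``beta_y`` on
``beta_x`` through the origin with weights ``1/se_y^2``, and — under
standard conditions — the summary-level equivalent of a two-stage
genetic-risk-score estimate from individual-level data.

MR-Egger relaxes the exclusion restriction: it fits the same weighted
regression with a free intercept, whose deviation from zero measures
average directional pleiotropy per SNP.  Standard errors use a
multiplicative over-dispersion parameter forced to be at least 1, with
t-distributed tests on ``n - 2`` degrees of freedom.  Cochran's Q over
the Wald ratios is the IVW-based heterogeneity/pleiotropy test.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearInstrumentsError,
    DegenerateInstrumentError,
    EstimationInputError,
    InsufficientInstrumentsError,
)
from .records import (
    Z95,
    EggerResult,
    HarmonizedPair,
    HeterogeneityResult,
    MREstimate,
    OutcomeScale,
)

IVW_FIXED = "ivw_fixed"
MR_EGGER = "mr_egger"

_P_FLOOR = 1e-300  # keep reported p-values strictly positive


def retained_pairs(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    """Pairs that survived harmonisation (action is not a ``dropped_*``)."""
    return [p for p in pairs if p.retained]


def pairs_to_arrays(
    pairs: Sequence[HarmonizedPair],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract (beta_x, se_x, beta_y, se_y) arrays from retained pairs.

    Raises if the retained set is empty, spans several cohorts or mixes
    outcome scales, or contains a zero exposure effect (an invalid
    instrument, not a droppable one).
    """
    kept = retained_pairs(pairs)
    if not kept:
        raise EstimationInputError("no retained pairs to estimate from")
    cohorts = {p.cohort for p in kept}
    if len(cohorts) > 1:
        raise EstimationInputError(f"pairs span multiple cohorts: {sorted(cohorts)}")
    scales = {p.outcome_scale for p in kept}
    if len(scales) > 1:
        raise EstimationInputError("pairs mix outcome scales")
    for p in kept:
        if p.beta_x == 0:
            raise DegenerateInstrumentError(
                f"{p.snp_id}: exposure effect is exactly 0; Wald ratio undefined"
            )
    bx = np.array([p.beta_x for p in kept], dtype=float)
    sx = np.array([p.se_x for p in kept], dtype=float)
    by = np.array([p.beta_y for p in kept], dtype=float)
    sy = np.array([p.se_y for p in kept], dtype=float)
    return bx, sx, by, sy


def _pair_meta(pairs: Sequence[HarmonizedPair]) -> tuple[str, str, OutcomeScale]:
    kept = retained_pairs(pairs)
    traits = {p.trait for p in kept}
    trait = next(iter(traits)) if len(traits) == 1 else ""
    return trait, kept[0].cohort, kept[0].outcome_scale


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal estimate ``beta_y / beta_x`` and its standard error.

    The default first-order SE, ``se_y / |beta_x|``, ignores the exposure
    sampling error (the usual summary-data convention).  With
    ``second_order=True`` the delta-method term in ``se_x`` is added.
    """
    if pair.beta_x == 0:
        raise DegenerateInstrumentError(
            f"{pair.snp_id}: exposure effect is exactly 0; Wald ratio undefined"
        )
    ratio = pair.beta_y / pair.beta_x
    var = pair.se_y**2 / pair.beta_x**2
    if second_order:
        var += pair.beta_y**2 * pair.se_x**2 / pair.beta_x**4
    return ratio, math.sqrt(var)


def _two_sided_normal_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR))


def ivw_fixed_effects(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """Fixed-effects IVW combination of the per-SNP Wald ratios for one cohort.

    With a single instrument this reduces exactly to the Wald ratio.
    P-values use the standard-normal reference; the 95% CI uses the
    1.959964 multiplier on the log scale.
    """
    bx, _, by, sy = pairs_to_arrays(pairs)
    trait, cohort, scale = _pair_meta(pairs)
    if bx.size == 1:
        # single instrument: exactly the Wald ratio, not a one-term sum
        beta_hat = float(by[0] / bx[0])
        se_hat = float(sy[0] / abs(bx[0]))
    else:
        w = bx**2 / sy**2
        beta_hat = float(np.sum(bx * by / sy**2) / np.sum(w))
        se_hat = float(math.sqrt(1.0 / np.sum(w)))
    return MREstimate(
        trait=trait,
        cohort=cohort,
        method=IVW_FIXED,
        beta_hat=beta_hat,
        se_hat=se_hat,
        ratio_scale=math.exp(beta_hat),
        ci_low=math.exp(beta_hat - Z95 * se_hat),
        ci_high=math.exp(beta_hat + Z95 * se_hat),
        pvalue=_two_sided_normal_p(beta_hat / se_hat),
        n_snps=int(bx.size),
        outcome_scale=scale,
    )


def estimate_survival(pairs: Sequence[HarmonizedPair]) -> MREstimate:
    """IVW estimate for survival outcomes; the ratio scale is a hazard ratio.

    The arithmetic is identical to :func:`ivw_fixed_effects`; this entry
    point only enforces that the pairs carry log-hazard associations.
    """
    kept = retained_pairs(pairs)
    if kept and kept[0].outcome_scale is not OutcomeScale.LOG_HAZARD:
        raise EstimationInputError("estimate_survival requires log_hazard outcome pairs")
    return ivw_fixed_effects(pairs)


def mr_egger(pairs: Sequence[HarmonizedPair], min_instruments: int = 3) -> EggerResult:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Pairs are first oriented so every exposure effect is non-negative
    (negating both members of a pair, which leaves the Wald ratio
    unchanged).  The regression of beta_y on beta_x uses weights
    ``1/se_y^2``; the residual dispersion is estimated and floored at 1
    (multiplicative random-effects convention), and both coefficients are
    tested against t with ``n - 2`` df.
    """
    bx, _, by, sy = pairs_to_arrays(pairs)
    trait, cohort, _ = _pair_meta(pairs)
    n = bx.size
    if n < min_instruments:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= {min_instruments} instruments, got {n}"
        )
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    if np.ptp(x) == 0:
        raise CollinearInstrumentsError("all exposure effects identical after orientation")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    df = n - 2
    scale = float(np.sum(w * resid**2) / df)
    dispersion = max(1.0, scale)
    cov = np.linalg.inv(xtwx) * dispersion
    se = np.sqrt(np.diag(cov))
    t_int = coef[0] / se[0]
    t_slope = coef[1] / se[1]
    return EggerResult(
        trait=trait,
        cohort=cohort,
        intercept=float(coef[0]),
        se_intercept=float(se[0]),
        slope=float(coef[1]),
        se_slope=float(se[1]),
        p_intercept=float(max(2.0 * stats.t.sf(abs(t_int), df), _P_FLOOR)),
        p_slope=float(max(2.0 * stats.t.sf(abs(t_slope), df), _P_FLOOR)),
        df=df,
        n_snps=int(n),
    )


def cochran_q(pairs: Sequence[HarmonizedPair], ivw: MREstimate) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test of the Wald ratios around the IVW estimate.

    ``Q = sum_j w_j (ratio_j - beta_hat)^2`` with first-order weights
    ``w_j = beta_xj^2 / se_yj^2``; referred to chi-square on ``n - 1`` df.
    Excess Q indicates heterogeneity consistent with horizontal pleiotropy.
    """
    bx, _, by, sy = pairs_to_arrays(pairs)
    trait, cohort, _ = _pair_meta(pairs)
    n = bx.size
    if n < 2:
        raise EstimationInputError("Cochran's Q needs >= 2 instruments")
    if ivw.method != IVW_FIXED:
        raise EstimationInputError("cochran_q requires an ivw_fixed estimate")
    if ivw.n_snps != n or ivw.cohort != cohort:
        raise EstimationInputError(
            "ivw estimate does not match the supplied pairs "
            f"(n_snps {ivw.n_snps} vs {n}, cohort {ivw.cohort!r} vs {cohort!r})"
        )
    w = bx**2 / sy**2
    ratios = by / bx
    q = float(np.sum(w * (ratios - ivw.beta_hat) ** 2))
    dfree = n - 1
    return HeterogeneityResult(
        trait=trait,
        cohort=cohort,
        q_statistic=q,
        df=dfree,
        p_het=float(stats.chi2.sf(q, dfree)),
        n_snps=int(n),
    )
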