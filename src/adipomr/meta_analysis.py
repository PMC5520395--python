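"""Fixed-effects meta-analysis of per-cohort causal estimates.

The pooled estimate is the inverse-variance-weighted mean of the cohort
log-ORs (or log-HRs), ``beta_pooled = sum(w_i b_i) / sum(w_i)`` with
``w_i = 1/se_i^2`` and ``se_pooled = sqrt(1/sum(w_i))`` — the same model
behind the summary diamond of a forest plot.  Between-cohort Cochran's Q
and I^2 are reported descriptively alongside the fixed-effects pool.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
from scipy import stats

from .exceptions import EstimationInputError
from .records import SUMMARY_LABEL, Z95, ForestRow, MetaResult, MREstimate

_P_FLOOR = 1e-300


def meta_fixed(estimates: Sequence[MREstimate]) -> MetaResult:
    """Pool one trait's per-cohort estimates under a fixed-effects model.

    Requires at least one estimate, one per cohort, all from the same
    method and outcome scale.  With a single cohort the pool reproduces
    that cohort's estimate exactly.
    """
    if not estimates:
        raise EstimationInputError("no cohort estimates to pool")
    cohorts = [e.cohort for e in estimates]
    if len(set(cohorts)) != len(cohorts):
        raise EstimationInputError(f"duplicate cohorts in meta-analysis: {cohorts}")
    traits = {e.trait for e in estimates}
    if len(traits) != 1:
        raise EstimationInputError(f"meta-analysis spans multiple traits: {sorted(traits)}")
    if len({e.method for e in estimates}) != 1:
        raise EstimationInputError("meta-analysis mixes estimation methods")
    scales = {e.outcome_scale for e in estimates}
    if len(scales) != 1:
        raise EstimationInputError("meta-analysis mixes outcome scales")

    betas = np.array([e.beta_hat for e in estimates], dtype=float)
    w = np.array([1.0 / e.se_hat**2 for e in estimates], dtype=float)
    beta_pooled = float(np.sum(w * betas) / np.sum(w))
    se_pooled = float(math.sqrt(1.0 / np.sum(w)))
    k = len(estimates)
    q = float(np.sum(w * (betas - beta_pooled) ** 2))
    dfree = k - 1
    i2 = max(0.0, (q - dfree) / q) if q > 0 else 0.0
    z = beta_pooled / se_pooled
    return MetaResult(
        trait=next(iter(traits)),
        beta_pooled=beta_pooled,
        se_pooled=se_pooled,
        or_pooled=math.exp(beta_pooled),
        ci_low=math.exp(beta_pooled - Z95 * se_pooled),
        ci_high=math.exp(beta_pooled + Z95 * se_pooled),
        pvalue=float(max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR)),
        n_cohorts=k,
        cochran_q_cohorts=q,
        i_squared=i2,
        outcome_scale=next(iter(scales)),
    )


def forest_rows(estimates: Sequence[MREstimate], meta: MetaResult) -> list[ForestRow]:
    """Forest-plot rows: one box per cohort plus the pooled summary diamond.

    Weights are the inverse variances, so the cohort weights sum to the
    summary row's total weight (the plot convention of drawing box areas
    proportional to the weight).
    """
    if meta.trait not in {e.trait for e in estimates}:
        raise EstimationInputError("meta result does not belong to the supplied estimates")
    rows = [
        ForestRow(
            trait=e.trait,
            label=e.cohort,
            estimate_or=e.ratio_scale,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            weight=e.weight,
        )
        for e in estimates
    ]
    rows.append(
        ForestRow(
            trait=meta.trait,
            label=SUMMARY_LABEL,
            estimate_or=meta.or_pooled,
            ci_low=meta.ci_low,
            ci_high=meta.ci_high,
            weight=1.0 / meta.se_pooled**2,
        )
    )
    return rows
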