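import numpy as np
import pytest

from adipomr.records import HarmonizationAction, HarmonizedPair, OutcomeScale


def make_pair(
    snp="rs1",
    beta_x=0.1,
    se_x=0.01,
    beta_y=0.05,
    se_y=0.02,
    cohort="UK",
    trait="BMI",
    scale=OutcomeScale.LOG_ODDS,
    action=HarmonizationAction.AS_IS,
):
    return HarmonizedPair(
        snp_id=snp,
        cohort=cohort,
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
        action=action,
        trait=trait,
        outcome_scale=scale,
    )


def random_pairs(rng, n, cohort="UK", trait="BMI", scale=OutcomeScale.LOG_ODDS):
    """Random retained pairs with nonzero exposure effects."""
    bx = rng.normal(0.1, 0.05, n)
    bx[np.abs(bx) < 1e-3] = 1e-3
    by = rng.normal(0.0, 0.05, n)
    sy = rng.uniform(0.01, 0.1, n)
    sx = rng.uniform(0.002, 0.01, n)
    return [
        make_pair(
            snp=f"rs{i}",
            beta_x=float(bx[i]),
            se_x=float(sx[i]),
            beta_y=float(by[i]),
            se_y=float(sy[i]),
            cohort=cohort,
            trait=trait,
            scale=scale,
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
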