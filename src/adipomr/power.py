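"""Asymptotic power of two-sample MR with a binary outcome.

Under the normal approximation, the IVW estimate of the log odds ratio
per exposure s.d. has standard error approximately

    se = 1 / sqrt(n * r2 * phi * (1 - phi))

where ``n`` is the outcome GWAS size, ``phi`` the case fraction and
``r2`` the exposure variance explained by the instruments.  The power of
a two-sided level-``alpha`` test against a postulated odds ratio ``OR``
is then

    power = Phi( |log OR| * sqrt(n * r2 * phi * (1 - phi)) - z_{1 - alpha/2} )

which is symmetric in OR <-> 1/OR and, at the null OR = 1, reduces to
the one-tailed rejection rate ``alpha / 2``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence

import pandas as pd
from scipy import stats

from .records import PowerScenario


def mr_power(scenario: PowerScenario) -> float:
    """Power of the IVW test for the given scenario, as a fraction in (0, 1)."""
    phi = scenario.case_fraction
    ncp = abs(math.log(scenario.or_per_sd)) * math.sqrt(
        scenario.n_total * scenario.r_squared * phi * (1.0 - phi)
    )
    z_crit = stats.norm.ppf(1.0 - scenario.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))


def power_curve(
    n_cases: int,
    n_controls: int,
    or_grid: Sequence[float] | Iterable[float],
    r_squared_grid: Sequence[float] | Iterable[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate :func:`mr_power` on a grid of (odds ratio, r^2) values.

    Returns a DataFrame with columns ``or_per_sd, r_squared, power``,
    ordered by (or_per_sd, r_squared).
    """
    or_values = sorted(or_grid)
    r2_values = sorted(r_squared_grid)
    if not or_values or not r2_values:
        raise ValueError("power_curve needs a non-empty grid")
    rows = [
        {
            "or_per_sd": orv,
            "r_squared": r2,
            "power": mr_power(
                PowerScenario(
                    n_cases=n_cases,
                    n_controls=n_controls,
                    r_squared=r2,
                    or_per_sd=orv,
                    alpha=alpha,
                )
            ),
        }
        for orv in or_values
        for r2 in r2_values
    ]
    return pd.DataFrame(rows, columns=["or_per_sd", "r_squared", "power"])
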