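"""Allele harmonisation of exposure and outcome summary statistics.

Two-sample MR combines per-SNP effects taken from different GWAS, which
may report the same variant with the alleles swapped or on the opposite
strand.  Harmonisation orients every outcome association to the
exposure's effect allele: the exposure orientation is canonical and is
never changed, so instrument effect signs stay stable across cohorts.

Palindromic variants (A/T or C/G) cannot be strand-resolved from the
allele labels, so they are kept only when the effect-allele frequencies
on both sides agree in direction and are far enough from 0.5 to be
informative; otherwise they are dropped.  With a missing frequency on
either side a palindromic SNP is always dropped.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .records import (
    HarmonizationAction,
    HarmonizedPair,
    InstrumentRecord,
    OutcomeRecord,
    OutcomeScale,
)

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default exclusion band half-width: palindromic SNPs with either EAF in
#: [0.42, 0.58] are considered ambiguous and dropped.
DEFAULT_PALINDROMIC_EAF_LIMIT = 0.42

_NAN = float("nan")


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be inferred."""
    return COMPLEMENT[a1] == a2


def _dropped(
    inst: InstrumentRecord, cohort: str, scale, action: HarmonizationAction
) -> HarmonizedPair:
    if scale is None:
        scale = OutcomeScale.LOG_ODDS
    return HarmonizedPair(
        snp_id=inst.snp_id,
        cohort=cohort,
        beta_x=inst.beta_exposure,
        se_x=inst.se_exposure,
        beta_y=_NAN,
        se_y=_NAN,
        action=action,
        trait=inst.trait,
        outcome_scale=scale,
    )


def _harmonize_one(
    inst: InstrumentRecord,
    out: OutcomeRecord,
    limit: float,
) -> HarmonizedPair:
    ea, oa = inst.effect_allele, inst.other_allele
    ea2, oa2 = out.effect_allele, out.other_allele
    scale = out.outcome_scale

    if is_palindromic(ea, oa):
        # For a palindromic exposure pair, the only compatible outcome
        # labels are the same two bases (complementing merely swaps them).
        if {ea2, oa2} != {ea, oa}:
            log.warning("%s: incompatible alleles %s/%s vs %s/%s", inst.snp_id, ea, oa, ea2, oa2)
            return _dropped(inst, out.cohort, scale, HarmonizationAction.DROPPED_INCOMPATIBLE)
        # Nominal alignment by allele label (order swap implies sign flip).
        if ea2 == ea:
            beta_y, eaf_y = out.beta_outcome, out.eaf
            action = HarmonizationAction.AS_IS
        else:
            beta_y = -out.beta_outcome
            eaf_y = None if out.eaf is None else 1.0 - out.eaf
            action = HarmonizationAction.SIGN_FLIPPED
        eaf_x = inst.eaf
        if eaf_x is None or eaf_y is None:
            return _dropped(inst, out.cohort, scale, HarmonizationAction.DROPPED_PALINDROMIC)
        ambiguous = (limit <= eaf_x <= 1 - limit) or (limit <= eaf_y <= 1 - limit)
        sides_agree = (eaf_x < 0.5) == (eaf_y < 0.5)
        if ambiguous or not sides_agree:
            return _dropped(inst, out.cohort, scale, HarmonizationAction.DROPPED_PALINDROMIC)
    else:
        if (ea2, oa2) == (ea, oa):
            beta_y, action = out.beta_outcome, HarmonizationAction.AS_IS
        elif (ea2, oa2) == (oa, ea):
            beta_y, action = -out.beta_outcome, HarmonizationAction.SIGN_FLIPPED
        elif (COMPLEMENT[ea2], COMPLEMENT[oa2]) == (ea, oa):
            beta_y, action = out.beta_outcome, HarmonizationAction.STRAND_FLIPPED
        elif (COMPLEMENT[ea2], COMPLEMENT[oa2]) == (oa, ea):
            beta_y, action = -out.beta_outcome, HarmonizationAction.STRAND_AND_SIGN_FLIPPED
        else:
            log.warning("%s: incompatible alleles %s/%s vs %s/%s", inst.snp_id, ea, oa, ea2, oa2)
            return _dropped(inst, out.cohort, scale, HarmonizationAction.DROPPED_INCOMPATIBLE)

    return HarmonizedPair(
        snp_id=inst.snp_id,
        cohort=out.cohort,
        beta_x=inst.beta_exposure,
        se_x=inst.se_exposure,
        beta_y=beta_y,
        se_y=out.se_outcome,
        action=action,
        trait=inst.trait,
        outcome_scale=scale,
    )


def harmonize(
    instruments: Sequence[InstrumentRecord],
    outcomes: Iterable[OutcomeRecord],
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT,
    cohorts: Sequence[str] | None = None,
) -> list[HarmonizedPair]:
    """Align every (instrument, cohort) combination onto the exposure's
    effect allele.

    Returns one :class:`HarmonizedPair` per instrument per cohort present
    in ``outcomes``, in instrument order within each cohort.  Nothing is
    silently discarded: instruments missing from a cohort appear with
    action ``dropped_missing``, unresolvable palindromic SNPs with
    ``dropped_palindromic`` and irreconcilable allele pairs with
    ``dropped_incompatible``.

    By default the cohort set is inferred from ``outcomes``; pass
    ``cohorts`` explicitly so that a cohort contributing zero records
    still appears, with every instrument marked ``dropped_missing``.
    """
    if not 0 < palindromic_eaf_limit < 0.5:
        raise ValueError("palindromic_eaf_limit must be in (0, 0.5)")
    by_cohort: dict[str, dict[str, OutcomeRecord]] = {}
    if cohorts is not None:
        for cohort in cohorts:
            by_cohort[cohort] = {}
    for rec in outcomes:
        by_cohort.setdefault(rec.cohort, {})[rec.snp_id] = rec
    pairs: list[HarmonizedPair] = []
    for cohort, table in by_cohort.items():
        scales = {rec.outcome_scale for rec in table.values()}
        if len(scales) > 1:
            raise ValueError(f"cohort {cohort!r} mixes outcome scales")
        scale = next(iter(scales)) if scales else None
        for inst in instruments:
            out = table.get(inst.snp_id)
            if out is None:
                pairs.append(_dropped(inst, cohort, scale, HarmonizationAction.DROPPED_MISSING))
            else:
                pairs.append(_harmonize_one(inst, out, palindromic_eaf_limit))
    return pairs


def cohort_instrument_counts(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Tabulate retained and dropped instrument counts per cohort.

    The counts partition the input exactly; cohorts with zero retained
    SNPs are reported, not omitted.
    """
    drop_actions = [a for a in HarmonizationAction if not a.retained]
    columns = ["retained"] + [a.value for a in drop_actions]
    if not pairs:
        return pd.DataFrame(columns=columns).rename_axis("cohort")
    counts: dict[str, dict[str, int]] = {}
    for p in pairs:
        row = counts.setdefault(p.cohort, {c: 0 for c in columns})
        row["retained" if p.retained else p.action.value] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")[columns]
    df.index.name = "cohort"
    return df.sort_index()


def write_harmonization_report(pairs: Sequence[HarmonizedPair], path: str | Path) -> None:
    """Write the per-SNP audit trail (snp_id, trait, cohort, action)."""
    pd.DataFrame(
        [
            {"snp_id": p.snp_id, "trait": p.trait, "cohort": p.cohort, "action": p.action.value}
            for p in pairs
        ],
        columns=["snp_id", "trait", "cohort", "action"],
    ).to_csv(path, sep="\t", index=False)
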