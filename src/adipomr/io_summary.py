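"""Readers and writers for tab-delimited GWAS summary statistics and results.

GWAS summary formats are dialect-heavy, so every reader accepts a
``column_map`` overriding the default header names (SNP, EA, OA, EAF,
BETA, SE, P).  Missing values are written as ``.`` and floats are
serialised with 17 significant digits so write/read round-trips are
lossless.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd
from scipy import stats

from .exceptions import RecordValidationError, SummaryFormatError
from .records import (
    SUMMARY_LABEL,
    ForestRow,
    InstrumentRecord,
    MREstimate,
    OutcomeRecord,
    OutcomeScale,
    VALID_ALLELES,
)

log = logging.getLogger(__name__)

#: Default column names; keys are the internal field roles.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
}

_MISSING = {"", "."}
_FLOAT_FMT = "%.17g"


def _resolve_columns(column_map: dict[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise SummaryFormatError(f"unknown column-map roles: {sorted(unknown)}")
        cols.update(column_map)
    return cols


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SummaryFormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SummaryFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def _parse_float(value: str, name: str, line: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise RecordValidationError(f"cannot parse {name}={value!r} as a number", line)


def _parse_optional_float(value: str, name: str, line: int) -> float | None:
    if value.strip() in _MISSING:
        return None
    return _parse_float(value, name, line)


def _check_allele_field(value: str, name: str, line: int) -> str:
    allele = value.strip().upper()
    if allele not in VALID_ALLELES:
        raise RecordValidationError(f"{name}={value!r} is not one of A/C/G/T", line)
    return allele


def _check_p_beta_consistency(
    pvalue: float | None, beta: float, se: float, snp: str, line: int
) -> None:
    # Published P-values are routinely rounded; only wild inconsistency
    # (two orders of magnitude on the log10 scale) is worth a warning.
    if pvalue is None or pvalue <= 0:
        return
    implied = 2.0 * stats.norm.sf(abs(beta / se))
    if implied <= 0:
        return
    if abs(math.log10(pvalue) - math.log10(implied)) > 2:
        log.warning(
            "%s (line %d): reported P=%.3g inconsistent with |beta/se| (implies P=%.3g)",
            snp,
            line,
            pvalue,
            implied,
        )


def read_instruments(
    path: str | Path,
    trait: str,
    column_map: dict[str, str] | None = None,
) -> list[InstrumentRecord]:
    """Read a tab-delimited table of exposure instruments for one trait.

    Duplicate SNP identifiers within a trait are an error.  EAF and P
    columns are optional; absent or ``.`` values become ``None``.
    """
    cols = _resolve_columns(column_map)
    required = [cols[k] for k in ("snp", "effect_allele", "other_allele", "beta", "se")]
    df = _read_table(path, required)
    records: list[InstrumentRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        row_d = dict(zip(df.columns, row))
        snp = str(row_d[cols["snp"]]).strip()
        if snp in seen:
            raise RecordValidationError(f"duplicate snp_id {snp!r} for trait {trait!r}", line)
        seen.add(snp)
        beta = _parse_float(row_d[cols["beta"]], "beta", line)
        se = _parse_float(row_d[cols["se"]], "se", line)
        if not se > 0:
            raise RecordValidationError(f"{snp}: se_exposure must be > 0, got {se}", line)
        eaf = (
            _parse_optional_float(row_d[cols["eaf"]], "eaf", line)
            if cols["eaf"] in df.columns
            else None
        )
        pvalue = (
            _parse_optional_float(row_d[cols["pvalue"]], "pvalue", line)
            if cols["pvalue"] in df.columns
            else None
        )
        _check_p_beta_consistency(pvalue, beta, se, snp, line)
        try:
            records.append(
                InstrumentRecord(
                    snp_id=snp,
                    effect_allele=_check_allele_field(row_d[cols["effect_allele"]], "EA", line),
                    other_allele=_check_allele_field(row_d[cols["other_allele"]], "OA", line),
                    beta_exposure=beta,
                    se_exposure=se,
                    eaf=eaf,
                    pvalue_exposure=pvalue,
                    trait=trait,
                )
            )
        except ValueError as exc:
            raise RecordValidationError(str(exc), line) from exc
    return records


def read_outcomes(
    path: str | Path,
    cohort: str,
    outcome_scale: OutcomeScale | str = OutcomeScale.LOG_ODDS,
    column_map: dict[str, str] | None = None,
) -> list[OutcomeRecord]:
    """Read a tab-delimited table of outcome associations for one cohort."""
    outcome_scale = OutcomeScale(outcome_scale)
    cols = _resolve_columns(column_map)
    required = [cols[k] for k in ("snp", "effect_allele", "other_allele", "beta", "se")]
    df = _read_table(path, required)
    if df.empty:
        log.warning("%s: no data rows for cohort %s", path, cohort)
    records: list[OutcomeRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        row_d = dict(zip(df.columns, row))
        snp = str(row_d[cols["snp"]]).strip()
        if snp in seen:
            raise RecordValidationError(f"duplicate snp_id {snp!r} in cohort {cohort!r}", line)
        seen.add(snp)
        beta = _parse_float(row_d[cols["beta"]], "beta", line)
        se = _parse_float(row_d[cols["se"]], "se", line)
        if not se > 0:
            raise RecordValidationError(f"{snp}: se_outcome must be > 0, got {se}", line)
        eaf = (
            _parse_optional_float(row_d[cols["eaf"]], "eaf", line)
            if cols["eaf"] in df.columns
            else None
        )
        try:
            records.append(
                OutcomeRecord(
                    snp_id=snp,
                    effect_allele=_check_allele_field(row_d[cols["effect_allele"]], "EA", line),
                    other_allele=_check_allele_field(row_d[cols["other_allele"]], "OA", line),
                    beta_outcome=beta,
                    se_outcome=se,
                    eaf=eaf,
                    cohort=cohort,
                    outcome_scale=outcome_scale,
                )
            )
        except ValueError as exc:
            raise RecordValidationError(str(exc), line) from exc
    return records


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "."
    return _FLOAT_FMT % value


def write_instruments(records: Iterable[InstrumentRecord], path: str | Path) -> None:
    """Write instruments in the same format :func:`read_instruments` accepts."""
    rows = [
        {
            "SNP": r.snp_id,
            "EA": r.effect_allele,
            "OA": r.other_allele,
            "EAF": _fmt(r.eaf),
            "BETA": _fmt(r.beta_exposure),
            "SE": _fmt(r.se_exposure),
            "P": _fmt(r.pvalue_exposure),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["SNP", "EA", "OA", "EAF", "BETA", "SE", "P"]).to_csv(
        path, sep="\t", index=False
    )


def write_outcomes(records: Iterable[OutcomeRecord], path: str | Path) -> None:
    """Write outcome associations in the format :func:`read_outcomes` accepts."""
    rows = [
        {
            "SNP": r.snp_id,
            "EA": r.effect_allele,
            "OA": r.other_allele,
            "EAF": _fmt(r.eaf),
            "BETA": _fmt(r.beta_outcome),
            "SE": _fmt(r.se_outcome),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["SNP", "EA", "OA", "EAF", "BETA", "SE"]).to_csv(
        path, sep="\t", index=False
    )


FOREST_COLUMNS = ["trait", "label", "estimate", "ci_low", "ci_high", "weight"]


def write_forest_data(rows: Sequence[ForestRow], path: str | Path) -> None:
    """Write forest-plot rows: one line per cohort box plus one summary diamond
    per trait.  Exactly one summary row per trait is required."""
    if not rows:
        raise SummaryFormatError("no forest rows to write")
    counts: dict[str, int] = {}
    for r in rows:
        counts.setdefault(r.trait, 0)
        if r.is_summary:
            counts[r.trait] += 1
    bad = {t: k for t, k in counts.items() if k != 1}
    if bad:
        raise SummaryFormatError(f"each trait needs exactly one summary row, got {bad}")
    df = pd.DataFrame(
        [
            {
                "trait": r.trait,
                "label": r.label,
                "estimate": _fmt(r.estimate_or),
                "ci_low": _fmt(r.ci_low),
                "ci_high": _fmt(r.ci_high),
                "weight": _fmt(r.weight),
            }
            for r in rows
        ],
        columns=FOREST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_forest_data(path: str | Path) -> list[ForestRow]:
    df = _read_table(path, FOREST_COLUMNS)
    return [
        ForestRow(
            trait=str(r["trait"]),
            label=str(r["label"]),
            estimate_or=float(r["estimate"]),
            ci_low=float(r["ci_low"]),
            ci_high=float(r["ci_high"]),
            weight=float(r["weight"]),
        )
        for _, r in df.iterrows()
    ]


ESTIMATE_COLUMNS = [
    "trait",
    "cohort",
    "method",
    "n_snps",
    "beta",
    "se",
    "ratio",
    "ci_low",
    "ci_high",
    "p",
    "outcome_scale",
]


def write_estimates(estimates: Sequence[MREstimate], path: str | Path) -> None:
    """Write causal estimates as a tab-delimited results table."""
    df = pd.DataFrame(
        [
            {
                "trait": e.trait,
                "cohort": e.cohort,
                "method": e.method,
                "n_snps": e.n_snps,
                "beta": _fmt(e.beta_hat),
                "se": _fmt(e.se_hat),
                "ratio": _fmt(e.ratio_scale),
                "ci_low": _fmt(e.ci_low),
                "ci_high": _fmt(e.ci_high),
                "p": _fmt(e.pvalue),
                "outcome_scale": e.outcome_scale.value,
            }
            for e in estimates
        ],
        columns=ESTIMATE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_estimates(path: str | Path) -> list[MREstimate]:
    df = _read_table(path, ESTIMATE_COLUMNS)
    return [
        MREstimate(
            trait=str(r["trait"]),
            cohort=str(r["cohort"]),
            method=str(r["method"]),
            beta_hat=float(r["beta"]),
            se_hat=float(r["se"]),
            ratio_scale=float(r["ratio"]),
            ci_low=float(r["ci_low"]),
            ci_high=float(r["ci_high"]),
            pvalue=float(r["p"]),
            n_snps=int(r["n_snps"]),
            outcome_scale=OutcomeScale(str(r["outcome_scale"])),
        )
        for _, r in df.iterrows()
    ]


def summary_label() -> str:
    return SUMMARY_LABEL
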