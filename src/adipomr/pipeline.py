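"""End-to-end orchestration: ingest/simulate -> harmonize -> estimate ->
meta-analyse -> pleiotropy tests, with reproducible seeds and a manifest.

Per trait the pipeline computes one IVW estimate per contributing cohort,
pools them under a fixed-effects model, and assesses pleiotropy with
Cochran's Q and the MR-Egger intercept on SNP-level associations pooled
across cohorts (each SNP's outcome effect inverse-variance-combined over
the cohorts where it was retained).  Cohorts that retain zero
instruments for a trait are excluded from the pool and counted — the
behaviour expected when an instrument set is simply absent from some
outcome GWASs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimators import (
    cochran_q,
    estimate_survival,
    ivw_fixed_effects,
    mr_egger,
    retained_pairs,
)
from .exceptions import AdipoMRError, InsufficientInstrumentsError
from .harmonization import (
    DEFAULT_PALINDROMIC_EAF_LIMIT,
    cohort_instrument_counts,
    harmonize,
    write_harmonization_report,
)
from .io_summary import read_instruments, read_outcomes, write_estimates, write_forest_data
from .meta_analysis import forest_rows, meta_fixed
from .records import (
    EggerResult,
    ForestRow,
    HarmonizedPair,
    HeterogeneityResult,
    MetaResult,
    MREstimate,
    OutcomeScale,
)
from .synthetic import SimulationTruth, simulate_study

log = logging.getLogger(__name__)

POOLED_COHORT = "pooled"


@dataclass(frozen=True)
class FileInputs:
    """File-based inputs for one trait: an instrument table and one
    outcome table per cohort."""

    instrument_path: str
    outcome_paths: dict[str, str]  # cohort -> path


@dataclass
class RunConfig:
    """Configuration of a full multi-trait analysis run.

    Exactly one of ``simulation`` (trait -> generating truth) or
    ``files`` (trait -> file inputs) must be provided.
    """

    traits: list[str]
    simulation: dict[str, SimulationTruth] | None = None
    files: dict[str, FileInputs] | None = None
    outcome_scale: OutcomeScale = OutcomeScale.LOG_ODDS
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT
    run_egger: bool = True
    min_egger_snps: int = 3
    alpha: float = 0.05
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    column_map: dict[str, str] | None = None

    def __post_init__(self):
        if not self.traits:
            raise ValueError("at least one trait is required")
        if (self.simulation is None) == (self.files is None):
            raise ValueError("exactly one of simulation/files must be given")
        source = self.simulation if self.simulation is not None else self.files
        missing = [t for t in self.traits if t not in source]
        if missing:
            raise ValueError(f"no inputs configured for trait(s) {missing}")


@dataclass
class TraitResult:
    """Everything the pipeline computed for one trait."""

    trait: str
    pairs: list[HarmonizedPair]
    cohort_estimates: list[MREstimate]
    dropped_cohorts: list[str]
    meta: MetaResult | None
    heterogeneity: HeterogeneityResult | None
    egger: EggerResult | None
    forest: list[ForestRow]
    error: str | None = None


@dataclass
class PipelineResult:
    traits: dict[str, TraitResult]
    config_hash: str
    seed: int


def pool_pairs_across_cohorts(pairs: list[HarmonizedPair]) -> list[HarmonizedPair]:
    """Fixed-effects pooling of each SNP's outcome association across cohorts.

    Produces one harmonized pair per SNP under the pseudo-cohort label
    ``pooled`` — the per-SNP statistics the trait-wise pleiotropy tests
    run on.  SNPs retained in no cohort are omitted.
    """
    by_snp: dict[str, list[HarmonizedPair]] = {}
    order: list[str] = []
    for p in retained_pairs(pairs):
        if p.snp_id not in by_snp:
            order.append(p.snp_id)
        by_snp.setdefault(p.snp_id, []).append(p)
    pooled: list[HarmonizedPair] = []
    for snp in order:
        group = by_snp[snp]
        w = np.array([1.0 / g.se_y**2 for g in group])
        by = np.array([g.beta_y for g in group])
        pooled.append(
            dataclasses.replace(
                group[0],
                cohort=POOLED_COHORT,
                beta_y=float(np.sum(w * by) / np.sum(w)),
                se_y=float(math.sqrt(1.0 / np.sum(w))),
            )
        )
    return pooled


def _load_trait_data(config: RunConfig, trait: str):
    if config.simulation is not None:
        truth = config.simulation[trait]
        study = simulate_study(truth, trait=trait)
        return study.instruments, study.all_outcomes, [c.name for c in truth.cohorts]
    inputs = config.files[trait]
    instruments = read_instruments(inputs.instrument_path, trait, column_map=config.column_map)
    outcomes = []
    for cohort, path in inputs.outcome_paths.items():
        outcomes.extend(
            read_outcomes(path, cohort, config.outcome_scale, column_map=config.column_map)
        )
    return instruments, outcomes, list(inputs.outcome_paths)


def analyze_trait(
    trait: str,
    pairs: list[HarmonizedPair],
    run_egger: bool = True,
    min_egger_snps: int = 3,
) -> TraitResult:
    """Estimate, pool and test one trait from its harmonized pairs."""
    by_cohort: dict[str, list[HarmonizedPair]] = {}
    for p in pairs:
        by_cohort.setdefault(p.cohort, []).append(p)
    estimates: list[MREstimate] = []
    dropped: list[str] = []
    for cohort, cohort_pairs in by_cohort.items():
        kept = retained_pairs(cohort_pairs)
        if not kept:
            dropped.append(cohort)
            log.info("%s: cohort %s retained 0 instruments; excluded", trait, cohort)
            continue
        if kept[0].outcome_scale is OutcomeScale.LOG_HAZARD:
            estimates.append(estimate_survival(cohort_pairs))
        else:
            estimates.append(ivw_fixed_effects(cohort_pairs))
        log.info("%s: cohort %s retained %d instruments", trait, cohort, len(kept))

    if not estimates:
        return TraitResult(
            trait=trait,
            pairs=pairs,
            cohort_estimates=[],
            dropped_cohorts=dropped,
            meta=None,
            heterogeneity=None,
            egger=None,
            forest=[],
            error="zero contributing cohorts",
        )

    meta = meta_fixed(estimates)
    forest = forest_rows(estimates, meta)

    pooled = pool_pairs_across_cohorts(pairs)
    heterogeneity = None
    egger = None
    if len(pooled) >= 2:
        pooled_ivw = ivw_fixed_effects(pooled)
        heterogeneity = cochran_q(pooled, pooled_ivw)
    if run_egger:
        try:
            egger = mr_egger(pooled, min_instruments=min_egger_snps)
        except InsufficientInstrumentsError:
            log.info("%s: < %d pooled instruments; MR-Egger skipped", trait, min_egger_snps)
    return TraitResult(
        trait=trait,
        pairs=pairs,
        cohort_estimates=estimates,
        dropped_cohorts=dropped,
        meta=meta,
        heterogeneity=heterogeneity,
        egger=egger,
        forest=forest,
    )


def _config_hash(config: RunConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, OutcomeScale):
            return obj.value
        if isinstance(obj, Path):
            return str(obj)
        return str(obj)

    fields = dataclasses.asdict(config)
    # the analysis is identified by its inputs, not by where results land
    fields.pop("output_dir", None)
    fields.pop("log_level", None)
    payload = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_trait_analysis(config: RunConfig) -> PipelineResult:
    """Run the full analysis for every configured trait.

    Deterministic given config + seed.  A trait whose every cohort drops
    all instruments is flagged with a trait-level error and the run
    continues.  When ``output_dir`` is set, results tables, forest data,
    the harmonisation audit and a manifest are written there.
    """
    logging.getLogger("adipomr").setLevel(config.log_level)
    results: dict[str, TraitResult] = {}
    for trait in config.traits:
        try:
            instruments, outcomes, cohort_names = _load_trait_data(config, trait)
        except (OSError, AdipoMRError) as exc:
            raise AdipoMRError(f"failed to load inputs for trait {trait!r}: {exc}") from exc
        pairs = harmonize(
            instruments, outcomes, config.palindromic_eaf_limit, cohorts=cohort_names
        )
        counts = cohort_instrument_counts(pairs)
        log.info("%s instrument counts:\n%s", trait, counts.to_string())
        result = analyze_trait(
            trait, pairs, run_egger=config.run_egger, min_egger_snps=config.min_egger_snps
        )
        if result.error:
            log.warning("%s: %s", trait, result.error)
        results[trait] = result
    pipeline = PipelineResult(traits=results, config_hash=_config_hash(config), seed=config.seed)
    if config.output_dir is not None:
        write_outputs(pipeline, config)
    return pipeline


def run_survival_analysis(config: RunConfig) -> PipelineResult:
    """Survival variant of :func:`run_trait_analysis` (log-HR outcomes)."""
    if config.outcome_scale is not OutcomeScale.LOG_HAZARD:
        raise ValueError("run_survival_analysis requires outcome_scale log_hazard")
    if config.simulation is not None:
        for trait, truth in config.simulation.items():
            if truth.outcome_scale is not OutcomeScale.LOG_HAZARD:
                raise ValueError(f"simulation truth for {trait!r} is not on the log_hazard scale")
    return run_trait_analysis(config)


def meta_table(pipeline: PipelineResult) -> pd.DataFrame:
    """Trait-level summary table: pooled ratio, CI, P (plus a Bonferroni
    column across the analysed traits, reported for transparency)."""
    n_traits = len(pipeline.traits)
    rows = []
    for trait, res in pipeline.traits.items():
        if res.meta is None:
            rows.append({"trait": trait, "error": res.error})
            continue
        m = res.meta
        rows.append(
            {
                "trait": trait,
                "ratio": m.or_pooled,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "p": m.pvalue,
                "p_bonferroni": min(1.0, m.pvalue * n_traits),
                "n_cohorts": m.n_cohorts,
                "q_cohorts": m.cochran_q_cohorts,
                "i_squared": m.i_squared,
                "scale": m.outcome_scale.ratio_label,
                "error": "",
            }
        )
    return pd.DataFrame(rows)


def pleiotropy_table(pipeline: PipelineResult) -> pd.DataFrame:
    """Per-trait pleiotropy assessment: IVW Cochran's Q and Egger intercept."""
    rows = []
    for trait, res in pipeline.traits.items():
        row: dict = {"trait": trait}
        if res.heterogeneity is not None:
            row.update(
                q=res.heterogeneity.q_statistic,
                q_df=res.heterogeneity.df,
                p_ivw_q=res.heterogeneity.p_het,
            )
        if res.egger is not None:
            row.update(
                egger_intercept=res.egger.intercept,
                se_intercept=res.egger.se_intercept,
                p_egger_intercept=res.egger.p_intercept,
                egger_slope=res.egger.slope,
                p_egger_slope=res.egger.p_slope,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(pipeline: PipelineResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_estimates = [e for r in pipeline.traits.values() for e in r.cohort_estimates]
    write_estimates(all_estimates, out / "estimates.tsv")
    all_forest = [f for r in pipeline.traits.values() for f in r.forest]
    if all_forest:
        write_forest_data(all_forest, out / "forest.tsv")
    all_pairs = [p for r in pipeline.traits.values() for p in r.pairs]
    write_harmonization_report(all_pairs, out / "harmonization.tsv")
    meta_table(pipeline).to_csv(out / "meta.tsv", sep="\t", index=False, float_format="%.17g")
    pleiotropy_table(pipeline).to_csv(
        out / "pleiotropy.tsv", sep="\t", index=False, float_format="%.17g"
    )
    manifest = [
        f"adipomr_version\t{__version__}",
        f"config_sha256\t{pipeline.config_hash}",
        f"seed\t{pipeline.seed}",
        f"traits\t{','.join(config.traits)}",
        f"mode\t{'simulation' if config.simulation is not None else 'files'}",
    ]
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
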