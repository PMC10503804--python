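"""End-to-end orchestration: simulate -> build scores -> tune -> annotate ->
scan, with a JSON run manifest (seed, config hash, row and exclusion counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import io
from .chip import annotate_chip_variants, derive_chip_variables, load_whitelist
from .scan import (carry_forward, interaction_scan, stratified_scan,
                   trait_scan, forest_table, z_matrix)
from .scores import build_grid_scores
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort
from .tuning import select_best_score


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    tuning: dict[str, object]
    retained_genes: list[str]
    scores: pd.DataFrame
    chip_vars: pd.DataFrame
    stratified: pd.DataFrame
    interactions: pd.DataFrame
    traits: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: CohortConfig | None = None, seed: int = 0,
                 chip_variables: list[str] | None = None,
                 alpha: float = 0.05, fdr: float = 0.05,
                 run_trait_scan: bool = False,
                 outdir: str | None = None) -> PipelineResult:
    """Run the whole discovery procedure on one synthetic cohort.

    Scores are built on the target cohort from external summary statistics,
    tuned against validation-cohort expression, and genes passing the
    r^2 > 1% retention rule enter the stratified scan; carried-forward pairs
    get interaction tests with BH FDR.
    """
    config = config or CohortConfig()
    cohort = simulate_cohort(config, seed)

    tuning: dict[str, object] = {}
    retained: list[str] = []
    score_cols = {"sample_id": cohort.genotypes.sample_ids}
    val_cov = None  # validation expression already noise + genetics only
    for gene in cohort.architectures:
        ss = cohort.sumstats[cohort.sumstats["gene_id"] == gene]
        target_cands = build_grid_scores(cohort.genotypes, ss, cohort.reference)
        val_cands = build_grid_scores(cohort.validation_genotypes, ss,
                                      cohort.reference)
        expr = pd.Series(cohort.validation_expression[gene].to_numpy(),
                         index=cohort.validation_expression["sample_id"],
                         name=gene)
        result = select_best_score(val_cands, {"validation": (expr, val_cov)})
        tuning[gene] = result
        if result.retained:
            retained.append(gene)
            best = next(c for c in target_cands
                        if c.config == result.best_config)
            score_cols[gene] = best.values
    scores = pd.DataFrame(score_cols)

    annotated, report = annotate_chip_variants(cohort.chip_calls)
    chip_vars = derive_chip_variables(annotated,
                                      list(cohort.genotypes.sample_ids))
    if chip_variables is None:
        chip_variables = ["has_chip"] + [g for g in ("DNMT3A", "TET2")
                                         if g in chip_vars.columns]

    stratified = stratified_scan(scores, chip_vars, cohort.phenotypes,
                                 chip_variables=chip_variables)
    stratified = carry_forward(stratified, alpha=alpha)
    flagged = stratified[stratified["carried_forward"]]
    interactions = interaction_scan(flagged, scores, chip_vars,
                                    cohort.phenotypes, fdr_alpha=fdr)
    traits = None
    if run_trait_scan and len(flagged):
        traits = trait_scan(flagged, scores, chip_vars, cohort.phenotypes,
                            fdr_alpha=fdr)

    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str)
            .encode()).hexdigest()[:16],
        "n_samples": config.n_samples,
        "n_genes_evaluated": len(cohort.architectures),
        "n_genes_retained": len(retained),
        "retained_genes": retained,
        "chip_calls_input": report.n_input,
        "chip_calls_retained": report.n_retained,
        "chip_exclusions": report.excluded,
        "whitelist_version": load_whitelist().version,
        "n_pairs": len(stratified),
        "n_carried_forward": int(stratified["carried_forward"].sum()),
    }

    result = PipelineResult(cohort=cohort, tuning=tuning, retained_genes=retained,
                            scores=scores, chip_vars=chip_vars,
                            stratified=stratified, interactions=interactions,
                            traits=traits, manifest=manifest)
    if outdir:
        write_outputs(result, outdir)
    return result


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["survival"] = asdict(config.resolved_survival())
    d["survival"]["interaction_log_hazards"] = {
        f"{k[0]}|{k[1]}": v
        for k, v in d["survival"]["interaction_log_hazards"].items()}
    d["planted_pair"] = list(d["planted_pair"])
    return d


def write_outputs(result: PipelineResult, outdir: str) -> None:
    io.ensure_dir(outdir)
    io.write_table(result.scores, f"{outdir}/scores.tsv")
    io.write_table(result.chip_vars, f"{outdir}/chip_variables.tsv")
    io.write_table(result.stratified, f"{outdir}/scan_results.tsv")
    io.write_table(forest_table(result.stratified), f"{outdir}/forest_data.tsv")
    if len(result.interactions):
        io.write_table(result.interactions, f"{outdir}/interactions.tsv")
        zm = z_matrix(result.interactions)
        if len(zm):
            zm.to_csv(f"{outdir}/interaction_z_matrix.tsv", sep="\t")
    if result.traits is not None:
        io.write_table(result.traits, f"{outdir}/trait_scan.tsv")
    rows = []
    for gene, t in result.tuning.items():
        rows.append({"gene_id": gene,
                     "best_config": t.best_config.label if t.best_config else "NA",
                     "best_r2": t.best_r2, "retained": t.retained})
    io.write_table(pd.DataFrame(rows), f"{outdir}/tuning.tsv")
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def write_cohort_inputs(cohort: SyntheticCohort, outdir: str,
                        as_vcf: bool = False) -> None:
    """Write every simulated input in its on-disk exchange format."""
    io.ensure_dir(outdir)
    io.write_sumstats(cohort.sumstats, f"{outdir}/sumstats.tsv")
    if as_vcf:
        io.write_vcf(cohort.reference, f"{outdir}/reference.vcf")
        io.write_vcf(cohort.genotypes, f"{outdir}/genotypes.vcf")
        io.write_vcf(cohort.validation_genotypes, f"{outdir}/validation_genotypes.vcf")
    else:
        io.write_dosage_tsv(cohort.reference, f"{outdir}/reference.tsv")
        io.write_dosage_tsv(cohort.genotypes, f"{outdir}/genotypes.tsv")
        io.write_dosage_tsv(cohort.validation_genotypes,
                            f"{outdir}/validation_genotypes.tsv")
    io.write_table(cohort.validation_expression, f"{outdir}/expression.tsv")
    io.write_table(cohort.chip_calls, f"{outdir}/chip_calls.tsv")
    io.write_table(cohort.phenotypes, f"{outdir}/phenotypes.tsv")
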