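"""Monte-Carlo validation experiments for the modifier-scan machinery.

These drive the package's own generators and fitters at study-condition
scale: type-I-error calibration of the interaction Wald test, CI coverage
for planted carrier-stratum and interaction effects, tuning recovery of a
known cis-heritability, and the end-to-end smoke success rate.  Both the
test suite and the acceptance script call these, so the numbers they report
are always produced by the same code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pipeline import run_pipeline
from .scan import CoxFitSpec, fit_cox
from .scores import build_grid_scores
from .synthetic import (CohortConfig, EqtlArchitecture, LdBlockSpec,
                        SurvivalModelSpec, calibrate_baseline_hazard,
                        linear_predictor, simulate_covariates,
                        simulate_expression, simulate_external_sumstats,
                        simulate_genotypes, simulate_ld_panel,
                        simulate_survival)
from .tuning import select_best_score

#: Study conditions of the calibration experiments: cohort size, carrier
#: prevalence, and marginal event fraction.
CALIBRATION_N = 20_000
CALIBRATION_PREVALENCE = 0.05
CALIBRATION_EVENT_FRACTION = 0.10

#: Adjustment set for the calibration simulations.  The Wald product-term
#: test's level does not depend on carrying the full covariate battery, so
#: the replicated fits adjust for the two covariates with planted hazard
#: effects.
CALIBRATION_COVARIATES = ["age", "sex"]
_CAL_COV_EFFECTS = {"age": 0.03, "sex": 0.3}


def _child_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence(entropy=int(seed),
                                      spawn_key=(i,)).generate_state(1)[0] % (2**31))


def simulate_interaction_cohort(seed: int, n: int = CALIBRATION_N,
                                carrier_prev: float = CALIBRATION_PREVALENCE,
                                event_frac: float = CALIBRATION_EVENT_FRACTION,
                                interaction: float = 0.0,
                                score_main: float = 0.0,
                                chip_main: float = math.log(1.18),
                                ) -> pd.DataFrame:
    """One cohort with an iid standardized score, a Bernoulli CHIP carrier
    indicator, and survival from the proportional-hazards generator."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(901,)))
    cov = simulate_covariates(n, seed)
    score = rng.standard_normal(n)
    carrier = (rng.uniform(size=n) < carrier_prev).astype(int)
    chip = pd.DataFrame({"sample_id": cov["sample_id"], "has_chip": carrier})
    scores = pd.DataFrame({"sample_id": cov["sample_id"], "score": score})
    spec = SurvivalModelSpec(
        covariate_log_hazards=dict(_CAL_COV_EFFECTS),
        chip_log_hazards={"has_chip": chip_main},
        score_log_hazards={"score": score_main},
        interaction_log_hazards={("has_chip", "score"): interaction},
    )
    lp = linear_predictor(spec, cov, chip, scores)
    spec = replace(spec, baseline_hazard=calibrate_baseline_hazard(
        spec, lp, event_frac))
    surv = simulate_survival(cov, chip, scores, spec, seed)
    d = cov.merge(chip, on="sample_id").merge(scores, on="sample_id") \
        .merge(surv, on="sample_id")
    d["interaction"] = d["has_chip"] * d["score"]
    return d


def interaction_type1_error(n_reps: int, seed: int, alpha: float = 0.05,
                            n: int = CALIBRATION_N,
                            carrier_prev: float = CALIBRATION_PREVALENCE,
                            event_frac: float = CALIBRATION_EVENT_FRACTION,
                            ) -> float:
    """Rejection rate of the product-term Wald test under a null interaction.

    Main effects (composite-CHIP log(1.18), covariate hazards) stay planted;
    only the interaction is zero.
    """
    spec = CoxFitSpec(covariates=CALIBRATION_COVARIATES,
                      exposures=["score", "has_chip", "interaction"])
    rejections = 0
    used = 0
    for i in range(n_reps):
        d = simulate_interaction_cohort(_child_seed(seed, i), n=n,
                                        carrier_prev=carrier_prev,
                                        event_frac=event_frac)
        out = fit_cox(d, spec)
        if out.flagged:
            continue
        used += 1
        if out.fit.summary().loc["interaction", "pvalue"] < alpha:
            rejections += 1
    return rejections / used if used else float("nan")


@dataclass
class CoverageResult:
    coverage_carrier_effect: float
    coverage_interaction: float
    mean_carrier_hr: float
    mean_interaction_coef: float
    n_reps: int


def interaction_coverage(n_reps: int, seed: int,
                         carrier_hr: float = 1.85,
                         n: int = CALIBRATION_N,
                         carrier_prev: float = CALIBRATION_PREVALENCE,
                         event_frac: float = CALIBRATION_EVENT_FRACTION,
                         ) -> CoverageResult:
    """95% CI coverage for a planted carrier-stratum score effect and for the
    interaction log-hazard (score effect zero among non-carriers)."""
    beta = math.log(carrier_hr)
    strat_spec = CoxFitSpec(covariates=CALIBRATION_COVARIATES,
                            exposures=["score"])
    inter_spec = CoxFitSpec(covariates=CALIBRATION_COVARIATES,
                            exposures=["score", "has_chip", "interaction"])
    cov_c = cov_i = used = 0
    hrs, coefs = [], []
    for i in range(n_reps):
        d = simulate_interaction_cohort(_child_seed(seed, i), n=n,
                                        carrier_prev=carrier_prev,
                                        event_frac=event_frac,
                                        interaction=beta)
        carriers = d[d["has_chip"] == 1]
        out_c = fit_cox(carriers, strat_spec)
        out_i = fit_cox(d, inter_spec)
        if out_c.flagged or out_i.flagged:
            continue
        used += 1
        s = out_c.fit.summary().loc["score"]
        if s["ci_low"] < carrier_hr < s["ci_high"]:
            cov_c += 1
        hrs.append(s["hr"])
        term = out_i.fit.summary().loc["interaction"]
        lo = math.log(term["ci_low"])
        hi = math.log(term["ci_high"])
        if lo < beta < hi:
            cov_i += 1
        coefs.append(term["coef"])
    return CoverageResult(
        coverage_carrier_effect=cov_c / used,
        coverage_interaction=cov_i / used,
        mean_carrier_hr=float(np.mean(hrs)),
        mean_interaction_coef=float(np.mean(coefs)),
        n_reps=used,
    )


@dataclass
class TuningRecovery:
    h2: float
    best_r2: float
    best_config_label: str
    retained: bool


def tuning_recovery(seed: int, h2: float = 0.35, n_external: int = 30_000,
                    n_validation: int = 5_000, n_reference: int = 2_000,
                    ) -> TuningRecovery:
    """Build the full candidate grid for a single-causal-variant gene and
    report the tuned best validation r^2 (target: close to h2)."""
    spec = LdBlockSpec(n_blocks=5, block_size=12)
    table = spec.variant_table()
    mid = spec.block_size // 2
    spec = replace(spec, gene_tss={"GENE": int(table["pos"].iloc[mid])})
    arch = EqtlArchitecture("GENE", [table["variant_id"].iloc[mid]], [1.0],
                            h2=h2)
    sumstats = simulate_external_sumstats(spec, arch, n_external, seed)
    reference = simulate_ld_panel(spec, 2 * n_reference, seed)
    validation = simulate_genotypes(spec, n_validation, seed, prefix="V",
                                    counter=500)
    expr = simulate_expression(validation, arch, seed, counter=7)
    cands = build_grid_scores(validation, sumstats, reference)
    res = select_best_score(cands, {"validation": (expr, None)})
    return TuningRecovery(h2=h2, best_r2=res.best_r2,
                          best_config_label=res.best_config.label
                          if res.best_config else "",
                          retained=res.retained)


@dataclass
class EffectRecovery:
    chip_hr: float
    carrier_stratum_hr: float
    noncarrier_stratum_hr: float
    interaction_z: float
    n: int


def planted_effect_recovery(seed: int, n: int = 150_000,
                            chip_hr: float = 1.18,
                            carrier_hr: float = 1.85,
                            noncarrier_hr: float = 0.99,
                            carrier_prev: float = CALIBRATION_PREVALENCE,
                            ) -> EffectRecovery:
    """Refit planted composite-CHIP and stratified score effects at large n.

    One cohort with score main effect log(noncarrier_hr), interaction
    log(carrier_hr/noncarrier_hr) and CHIP main effect log(chip_hr); the
    refits recover the three printed hazard ratios.
    """
    d = simulate_interaction_cohort(
        seed, n=n, carrier_prev=carrier_prev,
        interaction=math.log(carrier_hr) - math.log(noncarrier_hr),
        score_main=math.log(noncarrier_hr), chip_main=math.log(chip_hr))
    full = fit_cox(d, CoxFitSpec(covariates=CALIBRATION_COVARIATES,
                                 exposures=["score", "has_chip", "interaction"]))
    strat = CoxFitSpec(covariates=CALIBRATION_COVARIATES, exposures=["score"])
    carriers = fit_cox(d[d["has_chip"] == 1], strat)
    noncarriers = fit_cox(d[d["has_chip"] == 0], strat)
    return EffectRecovery(
        chip_hr=float(full.fit.summary().loc["has_chip", "hr"]),
        carrier_stratum_hr=float(carriers.fit.summary().loc["score", "hr"]),
        noncarrier_stratum_hr=float(noncarriers.fit.summary().loc["score", "hr"]),
        interaction_z=float(full.fit.summary().loc["interaction", "z"]),
        n=n,
    )


@dataclass
class SmokeOutcome:
    n_runs: int
    n_carried: int
    n_significant: int

    @property
    def success_rate(self) -> float:
        return self.n_significant / self.n_runs


def smoke_success(n_runs: int, seed: int,
                  config: CohortConfig | None = None) -> SmokeOutcome:
    """Fraction of seeded end-to-end runs in which the planted carrier-only
    pair is carried forward and FDR-significant."""
    config = config or CohortConfig()
    cv, gene = config.planted_pair
    carried = sig = 0
    for i in range(n_runs):
        res = run_pipeline(config, seed=_child_seed(seed, 7000 + i))
        st = res.stratified
        hit = st[(st["chip_variable"] == cv) & (st["gene"] == gene)]
        if len(hit) and bool(hit["carried_forward"].iloc[0]):
            carried += 1
            inter = res.interactions
            row = inter[(inter["chip_variable"] == cv) & (inter["gene"] == gene)]
            if len(row) and bool(row["interaction_significant"].iloc[0]):
                sig += 1
    return SmokeOutcome(n_runs=n_runs, n_carried=carried, n_significant=sig)
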