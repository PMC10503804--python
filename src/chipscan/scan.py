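"""Stratified survival scan, carry-forward rule, interaction testing, FDR.

The procedure, per (CHIP variable, gene score) pair:

1. *Stratified association* — fit a covariate-adjusted Cox model of the
   standardized score on the composite outcome separately among carriers and
   non-carriers of the CHIP variable, reporting per-SD hazard ratios.
2. *Carry-forward* — advance pairs whose score associates with the outcome
   (P < 0.05) among carriers **and not** among non-carriers (the strict
   two-clause reading; a one-clause variant is selectable).
3. *Interaction* — fit one hierarchical model (score + CHIP indicator +
   product term + covariates) on the full cohort; the product term's Wald z
   and P are the interaction statistics, with Benjamini–Hochberg FDR across
   the carried-forward family.
4. *Trait scan* — for flagged pairs, linear covariate-adjusted associations
   of the score with log2-transformed standardized quantitative traits among
   carriers, FDR-controlled separately within the hematologic (31-trait) and
   cardiometabolic (5-trait) families.

Adjustment covariates default to age, sex, ancestry, BMI, type-2-diabetes,
ever-smoker status and genetic PCs 1-10; rows with any missing adjusted
covariate are removed (complete-case) and the removed fraction is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cox import CoxConvergenceError, CoxFit, fit_cox_fast
from .synthetic import CARDIOMETABOLIC_TRAITS, COVARIATE_COLUMNS, HEMATOLOGIC_TRAITS

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = list(COVARIATE_COLUMNS)
ALPHA = 0.05


@dataclass
class CoxFitSpec:
    """Specification of one Cox model fit."""

    duration_col: str = "follow_time"
    event_col: str = "event"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    exposures: list[str] = field(default_factory=list)
    ties_method: str = "efron"


@dataclass
class FitOutcome:
    fit: CoxFit | None
    n_removed_missing: int
    removed_fraction: float
    flagged: str = ""  # non-empty on failure/non-convergence


def fit_cox(data: pd.DataFrame, spec: CoxFitSpec) -> FitOutcome:
    """Covariate-adjusted Cox fit with complete-case filtering and guards.

    Drops rows with a missing value in any model column and reports the
    removed fraction; requires at least one event and a non-constant
    exposure; attaches a convergence flag instead of raising on numerical
    failure (callers exclude flagged fits downstream).
    """
    if spec.ties_method != "efron":
        raise ValueError("only Efron tie handling is implemented")
    cols = [spec.duration_col, spec.event_col] + spec.covariates + spec.exposures
    sub = data[cols].dropna()
    n_removed = len(data) - len(sub)
    frac = n_removed / len(data) if len(data) else 0.0
    if n_removed:
        logger.info("complete-case filter removed %d rows (%.2f%%)",
                    n_removed, 100 * frac)
    if (sub[spec.duration_col] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if len(sub) == 0 or sub[spec.event_col].sum() == 0:
        return FitOutcome(None, n_removed, frac, flagged="no events")
    X = sub[spec.covariates + spec.exposures]
    for term in spec.exposures:
        if sub[term].nunique() < 2:
            return FitOutcome(None, n_removed, frac,
                              flagged=f"constant exposure {term}")
    try:
        fit = fit_cox_fast(sub[spec.duration_col].to_numpy(),
                           sub[spec.event_col].to_numpy(), X)
    except (CoxConvergenceError, FloatingPointError) as exc:
        return FitOutcome(None, n_removed, frac, flagged=str(exc))
    if not fit.converged or not np.all(np.isfinite(fit.se)):
        return FitOutcome(fit, n_removed, frac, flagged="non-convergence")
    return FitOutcome(fit, n_removed, frac)


# ------------------------------------------------------------ stratified scan

def stratified_scan(scores: pd.DataFrame, chip_vars: pd.DataFrame,
                    phenotypes: pd.DataFrame,
                    chip_variables: list[str] | None = None,
                    covariates: list[str] | None = None) -> pd.DataFrame:
    """Per-SD score-outcome associations among carriers and non-carriers.

    ``scores`` holds one standardized column per gene (plus ``sample_id``);
    ``chip_vars`` the 0/1 CHIP variables; ``phenotypes`` covariates plus
    ``follow_time``/``event``.  Pairs whose carrier stratum has no events
    are skipped with a reason.
    """
    covariates = list(DEFAULT_COVARIATES) if covariates is None else covariates
    chip_variables = chip_variables or [c for c in chip_vars.columns
                                        if c not in ("sample_id", "n_drivers")]
    genes = [c for c in scores.columns if c != "sample_id"]
    data = phenotypes.merge(chip_vars, on="sample_id").merge(scores, on="sample_id")
    rows = []
    for cv in chip_variables:
        for gene in genes:
            row = {"chip_variable": cv, "gene": gene, "skipped": ""}
            spec = CoxFitSpec(covariates=covariates, exposures=[gene])
            for label, mask in (("present", data[cv] == 1),
                                ("absent", data[cv] == 0)):
                stratum = data.loc[mask]
                if len(stratum) == 0 or stratum["event"].sum() == 0:
                    row["skipped"] = f"no events in {label} stratum"
                    continue
                out = fit_cox(stratum, spec)
                if out.flagged:
                    row["skipped"] = f"{label}: {out.flagged}"
                    continue
                s = out.fit.summary().loc[gene]
                row[f"hr_{label}"] = s["hr"]
                row[f"ci_low_{label}"] = s["ci_low"]
                row[f"ci_high_{label}"] = s["ci_high"]
                row[f"p_{label}"] = s["pvalue"]
                row[f"n_{label}"] = out.fit.n
                row[f"events_{label}"] = out.fit.n_events
            rows.append(row)
    return pd.DataFrame(rows)


def carry_forward(results: pd.DataFrame, alpha: float = ALPHA,
                  rule: str = "two-clause") -> pd.DataFrame:
    """Flag pairs advancing to interaction testing.

    ``two-clause`` (default): significant among carriers AND non-significant
    among non-carriers; ``one-clause``: significant among carriers only.
    """
    out = results.copy()
    present_sig = out["p_present"] < alpha
    absent_ns = out["p_absent"] >= alpha
    if rule == "two-clause":
        out["carried_forward"] = (present_sig & absent_ns).fillna(False)
    elif rule == "one-clause":
        out["carried_forward"] = present_sig.fillna(False)
    else:
        raise ValueError("rule must be 'two-clause' or 'one-clause'")
    out.loc[out["skipped"] != "", "carried_forward"] = False
    logger.info("carry-forward flagged %d of %d pairs",
                int(out["carried_forward"].sum()), len(out))
    return out


# ---------------------------------------------------------------- interaction

def interaction_scan(flagged: pd.DataFrame, scores: pd.DataFrame,
                     chip_vars: pd.DataFrame, phenotypes: pd.DataFrame,
                     covariates: list[str] | None = None,
                     fdr_alpha: float = ALPHA) -> pd.DataFrame:
    """Hierarchical interaction model per carried-forward pair.

    One model per pair: covariates + score + CHIP indicator + product term;
    ``interaction_z``/``interaction_p`` are the product term's Wald
    statistics and ``interaction_q`` the BH q-value across the flagged
    family.
    """
    covariates = list(DEFAULT_COVARIATES) if covariates is None else covariates
    data = phenotypes.merge(chip_vars, on="sample_id").merge(scores, on="sample_id")
    rows = []
    for _, pair in flagged.iterrows():
        cv, gene = pair["chip_variable"], pair["gene"]
        d = data.copy()
        prod = f"{cv}_x_{gene}"
        d[prod] = d[cv] * d[gene]
        spec = CoxFitSpec(covariates=covariates, exposures=[gene, cv, prod])
        out = fit_cox(d, spec)
        row = dict(pair)
        if out.flagged:
            row["interaction_flagged"] = out.flagged
            row["interaction_z"] = np.nan
            row["interaction_p"] = np.nan
        else:
            s = out.fit.summary().loc[prod]
            row["interaction_flagged"] = ""
            row["interaction_coef"] = s["coef"]
            row["interaction_z"] = s["z"]
            row["interaction_p"] = s["pvalue"]
            row["interaction_ci_low"] = np.log(s["ci_low"])
            row["interaction_ci_high"] = np.log(s["ci_high"])
        rows.append(row)
    res = pd.DataFrame(rows)
    if len(res):
        ok = res["interaction_p"].notna()
        q = np.full(len(res), np.nan)
        if ok.any():
            q[ok.to_numpy()] = bh_fdr(res.loc[ok, "interaction_p"].to_numpy())
        res["interaction_q"] = q
        res["interaction_significant"] = res["interaction_q"] < fdr_alpha
    return res


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in sorted p)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------- trait scan

def transform_trait(values: pd.Series, offset: float = 0.0) -> pd.Series:
    """log2-transform then standardize to zero mean, unit variance.

    ``offset`` is added before the log (the CRP convention is +1 so that
    zero measurements stay finite).  Non-positive values after the offset
    are dropped (returned as NaN) and counted by the caller; a constant
    transformed trait is degenerate and signalled with all-NaN.
    """
    x = values.astype(float) + offset
    out = pd.Series(np.where(x > 0, np.log2(np.where(x > 0, x, 1.0)), np.nan),
                    index=values.index, name=values.name)
    sd = out.std(ddof=0)
    # relative guard: a constant trait can carry an SD of ~1e-16 from
    # floating accumulation alone
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(out.mean())):
        return pd.Series(np.nan, index=values.index, name=values.name)
    return (out - out.mean()) / sd


def trait_scan(flagged: pd.DataFrame, scores: pd.DataFrame,
               chip_vars: pd.DataFrame, phenotypes: pd.DataFrame,
               hematologic: list[str] | None = None,
               cardiometabolic: list[str] | None = None,
               covariates: list[str] | None = None,
               fdr_alpha: float = ALPHA) -> pd.DataFrame:
    """Exploratory quantitative-trait scan for flagged pairs.

    For each pair x trait, a linear covariate-adjusted association of the
    standardized score with the transformed trait among carriers of the
    pair's CHIP variable.  BH FDR is applied separately within the
    hematologic and cardiometabolic families, so with ``k`` flagged pairs
    the family sizes are ``k * 31`` and ``k * 5`` under the default trait
    panels.
    """
    hematologic = HEMATOLOGIC_TRAITS if hematologic is None else hematologic
    cardiometabolic = CARDIOMETABOLIC_TRAITS if cardiometabolic is None \
        else cardiometabolic
    covariates = list(DEFAULT_COVARIATES) if covariates is None else covariates
    data = phenotypes.merge(chip_vars, on="sample_id").merge(scores, on="sample_id")
    families = [("hematologic", hematologic), ("cardiometabolic", cardiometabolic)]
    rows = []
    for _, pair in flagged.iterrows():
        cv, gene = pair["chip_variable"], pair["gene"]
        carriers = data.loc[data[cv] == 1]
        for family, traits in families:
            for trait in traits:
                offset = 1.0 if trait == "crp" else 0.0
                y = transform_trait(carriers[trait], offset=offset)
                row = {"chip_variable": cv, "gene": gene, "family": family,
                       "trait": trait}
                keep = y.notna() & carriers[gene].notna()
                n_dropped = int((~y.notna()).sum())
                row["n_dropped_nonpositive"] = n_dropped
                if y.notna().sum() == 0:
                    row["skipped"] = "degenerate trait"
                    rows.append(row)
                    continue
                sub = carriers.loc[keep]
                X = sm.add_constant(sub[[gene] + covariates].astype(float))
                fit = sm.OLS(y[keep], X).fit()
                row["beta"] = fit.params[gene]
                row["se"] = fit.bse[gene]
                row["pvalue"] = fit.pvalues[gene]
                row["n"] = int(fit.nobs)
                row["skipped"] = ""
                rows.append(row)
    res = pd.DataFrame(rows)
    if len(res):
        res["qvalue"] = np.nan
        for family, _ in families:
            mask = (res["family"] == family) & res["pvalue"].notna()
            if mask.any():
                res.loc[mask, "qvalue"] = bh_fdr(res.loc[mask, "pvalue"].to_numpy())
        res["significant"] = res["qvalue"] < fdr_alpha
    return res


# -------------------------------------------------------------- figure tables

def forest_table(results: pd.DataFrame) -> pd.DataFrame:
    """Long-format stratified-HR data (one row per pair x stratum)."""
    rows = []
    for _, r in results.iterrows():
        for label in ("present", "absent"):
            if f"hr_{label}" in r and pd.notna(r.get(f"hr_{label}", np.nan)):
                rows.append({
                    "chip_variable": r["chip_variable"], "gene": r["gene"],
                    "stratum": label, "hr": r[f"hr_{label}"],
                    "ci_low": r[f"ci_low_{label}"], "ci_high": r[f"ci_high_{label}"],
                    "pvalue": r[f"p_{label}"],
                })
    return pd.DataFrame(rows)


def z_matrix(interactions: pd.DataFrame) -> pd.DataFrame:
    """Interaction z scores pivoted to a (gene x CHIP variable) matrix."""
    if len(interactions) == 0:
        return pd.DataFrame()
    return interactions.pivot_table(index="gene", columns="chip_variable",
                                    values="interaction_z")
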