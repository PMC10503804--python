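"""Synthetic biobank cohort generator.

Every input the analysis consumes can be generated here: LD-structured
genotypes (a Gaussian-copula haplotype-block model), cis-eQTL architectures
with stated heritability, external-panel eQTL summary statistics, measured
expression for score tuning, CHIP carrier status with a clone-size (VAF)
distribution, baseline covariates, quantitative traits, and survival
outcomes drawn from a proportional-hazards model with planted
CHIP x gene-score interaction log-hazards.

Defaults mirror the published cohort the pipeline emulates: composite CHIP
prevalence 6.2% with 92.6% single-driver carriers, a JAK2 clone-size
distribution putting ~97% of JAK2 carriers above the 10% large-clone VAF
threshold, age 56.3 (SD 8.1) years, 44.4% male, ~10.6% composite CVD events
over an ~11-year follow-up, and a composite-CHIP hazard ratio of 1.18.

All generators are deterministic given (config, seed); the master seed is
fanned out to per-generator streams through ``numpy`` seed sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import DosageMatrix

CIS_WINDOW_BP = 500_000  # cis definition: +/- 500 kb around the TSS


class ParameterError(ValueError):
    """Invalid generator parameterization."""


class ConsistencyError(ValueError):
    """Inputs that disagree with each other (e.g. a causal variant absent)."""


# ------------------------------------------------------------------ seeding

_STREAMS = {
    "haplotypes": 1, "expression": 2, "sumstats": 3, "chip": 4,
    "covariates": 5, "survival": 6, "traits": 7,
}


def stream_rng(seed: int, stream: str, counter: int = 0) -> np.random.Generator:
    """Independent generator for one named stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_STREAMS[stream], int(counter))))


# ------------------------------------------------------------- LD block model

_ALLELE_PAIRS = [("G", "A"), ("A", "C"), ("C", "T"), ("T", "G")]  # (other, counted)


@dataclass
class LdBlockSpec:
    """Haplotype-block LD structure for one simulated chromosome.

    ``within_block_corr`` is the target pairwise *allele-level* correlation
    of haplotypes in the same block (so dosage r^2 within a block is about
    its square); blocks are mutually independent.  One minor-allele
    frequency is drawn per block from ``maf_range`` and shared by the
    block's variants, which keeps an exchangeable allele correlation
    attainable for any target below 1.
    """

    n_blocks: int = 5
    block_size: int = 12
    within_block_corr: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    spacing_bp: int = 20_000
    chrom: str = "1"
    start_pos: int = 1_000_000
    gene_tss: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ParameterError("need at least one block and one variant per block")
        if not (0 <= self.within_block_corr < 1):
            raise ParameterError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError("minor-allele frequencies must lie in (0, 0.5]")
        if self.spacing_bp < 1:
            raise ParameterError("spacing_bp must be positive")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size

    def positions(self) -> np.ndarray:
        """1-based physical positions, strictly increasing, evenly spaced."""
        return self.start_pos + self.spacing_bp * np.arange(self.n_variants)

    def block_of(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_blocks), self.block_size)

    def variant_table(self) -> pd.DataFrame:
        pos = self.positions()
        other, counted = zip(*(_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
                               for j in range(self.n_variants)))
        return pd.DataFrame({
            "variant_id": [f"{self.chrom}:{p}:{o}:{c}"
                           for p, o, c in zip(pos, other, counted)],
            "chrom": self.chrom,
            "pos": pos,
            "counted_allele": counted,
            "other_allele": other,
        })

    def tss_of(self, gene_id: str) -> int:
        try:
            return self.gene_tss[gene_id]
        except KeyError:
            raise ParameterError(f"no TSS registered for gene {gene_id!r}") from None


def _latent_rho(target_allele_corr: float, maf: float) -> float:
    """Latent-normal correlation whose dichotomized phi coefficient equals
    the target allele correlation (tetrachoric inversion, equal margins)."""
    if target_allele_corr <= 0:
        return 0.0
    z = stats.norm.ppf(maf)
    pq = maf * (1 - maf)

    def phi_minus_target(rho: float) -> float:
        p11 = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([z, z])
        return (p11 - maf * maf) / pq - target_allele_corr

    return optimize.brentq(phi_minus_target, 0.0, 1 - 1e-9, xtol=1e-6)


def block_mafs(spec: LdBlockSpec, seed: int) -> np.ndarray:
    """Per-block minor-allele frequencies of the simulated population.

    Drawn once from (spec, seed) so that the LD reference panel, target
    cohort, validation cohort, and external eQTL panel all sample the same
    population (same allele frequencies and LD)."""
    lo, hi = spec.maf_range
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(0, 999_983)))
    return rng.uniform(lo, hi, spec.n_blocks)


def _simulate_haplotypes(spec: LdBlockSpec, n_haplotypes: int,
                         rng: np.random.Generator,
                         mafs: np.ndarray) -> np.ndarray:
    """(n_haplotypes, n_variants) 0/1 allele matrix under the copula model."""
    out = np.empty((n_haplotypes, spec.n_variants), dtype=np.int8)
    for b in range(spec.n_blocks):
        maf = float(mafs[b])
        rho = _latent_rho(spec.within_block_corr, maf)
        cols = slice(b * spec.block_size, (b + 1) * spec.block_size)
        shared = rng.standard_normal((n_haplotypes, 1))
        noise = rng.standard_normal((n_haplotypes, spec.block_size))
        latent = math.sqrt(rho) * shared + math.sqrt(1 - rho) * noise
        out[:, cols] = latent < stats.norm.ppf(maf)
    return out


def simulate_ld_panel(spec: LdBlockSpec, n_haplotypes: int, seed: int) -> DosageMatrix:
    """Diploid LD reference panel: paired haplotypes summed to dosages."""
    if n_haplotypes % 2 or n_haplotypes < 2:
        raise ParameterError("n_haplotypes must be an even count >= 2")
    rng = stream_rng(seed, "haplotypes")
    hap = _simulate_haplotypes(spec, n_haplotypes, rng, block_mafs(spec, seed))
    dosages = (hap[0::2] + hap[1::2]).astype(float)
    n = n_haplotypes // 2
    return DosageMatrix(
        sample_ids=[f"REF{i:06d}" for i in range(n)],
        variants=spec.variant_table(),
        values=dosages,
    )


def simulate_genotypes(spec: LdBlockSpec, n_individuals: int, seed: int,
                       prefix: str = "S", counter: int = 0) -> DosageMatrix:
    """Target-cohort diploid genotypes (independent stream from the panel)."""
    rng = stream_rng(seed, "haplotypes", counter=counter + 1)
    hap = _simulate_haplotypes(spec, 2 * n_individuals, rng, block_mafs(spec, seed))
    return DosageMatrix(
        sample_ids=[f"{prefix}{i:06d}" for i in range(n_individuals)],
        variants=spec.variant_table(),
        values=(hap[0::2] + hap[1::2]).astype(float),
    )


# --------------------------------------------------------- eQTL architecture

@dataclass
class EqtlArchitecture:
    """Sparse cis-eQTL architecture of one gene.

    Expression is ``sqrt(h2) * standardized genetic value + sqrt(1-h2) * noise``,
    so genetics contributes exactly ``h2`` of unit variance.
    """

    gene_id: str
    causal_variant_ids: list[str]
    causal_effects: list[float]
    h2: float

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ParameterError("h2 must lie in [0, 1)")
        if len(self.causal_variant_ids) != len(self.causal_effects):
            raise ParameterError("one effect per causal variant required")

    def validate_against(self, spec: LdBlockSpec) -> None:
        tss = spec.tss_of(self.gene_id)
        table = spec.variant_table().set_index("variant_id")
        for vid in self.causal_variant_ids:
            if vid not in table.index:
                raise ConsistencyError(f"causal variant {vid} not in LD spec")
            if abs(int(table.loc[vid, "pos"]) - tss) > CIS_WINDOW_BP:
                raise ConsistencyError(
                    f"causal variant {vid} outside the cis window of {self.gene_id}")


def genetic_value(genotypes: DosageMatrix, arch: EqtlArchitecture) -> np.ndarray:
    """Standardized (mean 0, SD 1) genetic value of the architecture."""
    missing = [v for v in arch.causal_variant_ids if v not in genotypes._index]
    if missing:
        raise ConsistencyError(f"causal variants missing from genotypes: {missing}")
    if not arch.causal_variant_ids:
        return np.zeros(genotypes.n_samples)
    idx = [genotypes.column_index(v) for v in arch.causal_variant_ids]
    g = genotypes.values[:, idx] @ np.asarray(arch.causal_effects, dtype=float)
    sd = g.std()
    if sd == 0:
        raise ConsistencyError("genetic value is constant (monomorphic causal set)")
    return (g - g.mean()) / sd


def simulate_expression(genotypes: DosageMatrix, arch: EqtlArchitecture,
                        seed: int, counter: int = 0) -> pd.Series:
    """Per-individual expression with cis-heritability ``arch.h2``."""
    rng = stream_rng(seed, "expression", counter=counter)
    noise = rng.standard_normal(genotypes.n_samples)
    if arch.h2 == 0 or not arch.causal_variant_ids:
        y = noise
    else:
        g = genetic_value(genotypes, arch)
        y = math.sqrt(arch.h2) * g + math.sqrt(1 - arch.h2) * noise
    return pd.Series(y, index=pd.Index(genotypes.sample_ids, name="sample_id"),
                     name=arch.gene_id)


def simulate_external_sumstats(spec: LdBlockSpec, arch: EqtlArchitecture,
                               n_external: int, seed: int,
                               counter: int = 0) -> pd.DataFrame:
    """Marginal cis-eQTL summary statistics from an independent external panel.

    Simulates ``n_external`` fresh individuals under ``spec``, draws their
    expression under ``arch``, and regresses expression on each cis variant's
    dosage separately.  Monomorphic variants are emitted with missing effect
    fields (NA beta/se/pvalue) so downstream stages can drop them explicitly.
    """
    if n_external < 100:
        raise ParameterError("external panel must have at least 100 individuals")
    panel = simulate_genotypes(spec, n_external, seed, prefix="EXT",
                               counter=1000 + counter)
    y = simulate_expression(panel, arch, seed, counter=1000 + counter).to_numpy()
    tss = spec.tss_of(arch.gene_id)
    var_tab = panel.variants
    cis = np.abs(var_tab["pos"].to_numpy() - tss) <= CIS_WINDOW_BP
    G = panel.values[:, cis]
    sub = var_tab.loc[cis].reset_index(drop=True)

    n = G.shape[0]
    gm = G.mean(axis=0)
    Gc = G - gm
    sxx = (Gc ** 2).sum(axis=0)
    poly = sxx > 0
    yc = y - y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = Gc.T @ yc
        beta = np.where(poly, sxy / np.where(sxx > 0, sxx, np.nan), np.nan)
        syy = float((yc ** 2).sum())
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / np.where(sxx > 0, sxx, np.nan))
        tval = beta / se
    # log-space p values: the marginal t statistics at biobank-scale n are
    # large enough to underflow 2*sf(|t|), which would erase the P ordering
    # that clumping relies on
    with np.errstate(divide="ignore", invalid="ignore"):
        logsf = stats.t.logsf(np.abs(tval), df=n - 2)
        # t.logsf underflows to -inf for extreme statistics; the normal tail
        # (exact as df -> inf) stays finite in log space
        norm_logsf = stats.norm.logsf(np.abs(tval))
        logsf = np.where(np.isneginf(logsf), norm_logsf, logsf)
    log10p = (np.log(2.0) + logsf) / np.log(10.0)
    pval = np.maximum(2 * stats.t.sf(np.abs(tval), df=n - 2),
                      np.finfo(float).tiny)
    pval = np.where(np.isnan(tval), np.nan, pval)
    return pd.DataFrame({
        "gene_id": arch.gene_id,
        "variant_id": sub["variant_id"],
        "chrom": sub["chrom"],
        "pos": sub["pos"],
        "effect_allele": sub["counted_allele"],
        "other_allele": sub["other_allele"],
        "eaf": gm / 2.0,
        "beta": beta,
        "se": se,
        "pvalue": np.where(poly, pval, np.nan),
        "log10_pvalue": np.where(poly, log10p, np.nan),
        "n": n,
        "tss": tss,
    })


# ----------------------------------------------------------------- CHIP status

#: Marginal per-gene carrier probabilities. The sum equals
#: composite prevalence (6.2%) times the mean driver count (1.074, since
#: 92.6% of carriers hold a single driver mutation).
DEFAULT_GENE_PREVALENCE = {
    "DNMT3A": 0.03424,   # 55.4% of carriers
    "TET2": 0.01229,     # 19.9%
    "ASXL1": 0.00583,    # 9.1%
    "JAK2": 0.000594,    # 1.0%
    "SRSF2": 0.0011,
    "SF3B1": 0.0007,
    "TP53": 0.0011,
    "PPM1D": 0.0010,
    "OTHER": 0.009734,
}

DEFAULT_MULTI_DRIVER_RATE = 0.074  # fraction of carriers with 2 drivers

#: Clone-size (VAF) Beta(a, b) shapes, truncated to [0.02, 1].  JAK2 clones
#: are concentrated above the 10% large-clone threshold (~97% large); other
#: drivers give roughly 30% large clones.
DEFAULT_VAF_PARAMS: dict[str, tuple[float, float]] = {"JAK2": (4.0, 9.0)}
DEFAULT_VAF_SHAPE = (1.0, 14.0)
VAF_DETECTION_FLOOR = 0.02


def _driver_weights(targets: np.ndarray, multi_rate: float,
                    n_iter: int = 60) -> np.ndarray:
    """Single-draw gene weights whose realized per-gene marginals match the
    target prevalences under the two-draw multi-driver scheme.

    A carrier's second driver is redrawn until distinct from the first, which
    inflates small genes relative to the raw weights; the fixed point
    w_g = t_g / (1 + m * sum_{h != g} w_h / (1 - w_h)) undoes that.
    """
    t = targets / targets.sum()
    w = t.copy()
    if multi_rate <= 0 or len(w) < 2:
        return w
    for _ in range(n_iter):
        ratio = w / (1.0 - np.minimum(w, 1 - 1e-9))
        s = ratio.sum() - ratio
        w = t * (1.0 + multi_rate) / (1.0 + multi_rate * s)
        w = w / w.sum()
    return w


def _sample_vaf(gene: str, size: int, rng: np.random.Generator,
                vaf_params: dict[str, tuple[float, float]]) -> np.ndarray:
    a, b = vaf_params.get(gene, DEFAULT_VAF_SHAPE)
    dist = stats.beta(a, b)
    lo = dist.cdf(VAF_DETECTION_FLOOR)
    u = rng.uniform(lo, 1.0, size=size)
    return dist.ppf(u)


def simulate_chip_status(n_individuals: int,
                         prevalences: dict[str, float] | None = None,
                         multi_driver_rate: float = DEFAULT_MULTI_DRIVER_RATE,
                         vaf_params: dict[str, tuple[float, float]] | None = None,
                         seed: int = 0,
                         sample_ids: list[str] | None = None,
                         age: np.ndarray | None = None,
                         age_log_odds_per_year: float = 0.0) -> pd.DataFrame:
    """Somatic CHIP driver calls: columns ``sample_id, gene, protein_change, vaf``.

    Composite carrier status is Bernoulli with probability
    ``sum(prevalences) / (1 + multi_driver_rate)``; carriers draw one driver
    (or two, with probability ``multi_driver_rate``) from the prevalence
    weights, then a clone size from the gene's truncated Beta VAF
    distribution (all calls satisfy VAF >= 2% by construction).  Passing
    ``age`` with a nonzero ``age_log_odds_per_year`` tilts carrier
    probability on the age scale (off by default).
    """
    prevalences = dict(DEFAULT_GENE_PREVALENCE if prevalences is None else prevalences)
    vaf_params = dict(DEFAULT_VAF_PARAMS if vaf_params is None else vaf_params)
    for g, p in prevalences.items():
        if not (0 <= p <= 1):
            raise ParameterError(f"prevalence of {g} outside [0, 1]")
    rng = stream_rng(seed, "chip")
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n_individuals)]
    total = sum(prevalences.values())
    p_comp = total / (1.0 + multi_driver_rate)
    if total == 0:
        return pd.DataFrame(columns=["sample_id", "gene", "protein_change", "vaf"])
    if age is not None and age_log_odds_per_year != 0.0:
        logit = math.log(p_comp / (1 - p_comp)) \
            + age_log_odds_per_year * (np.asarray(age, float) - np.mean(age))
        p_i = 1.0 / (1.0 + np.exp(-logit))
        carrier = rng.uniform(size=n_individuals) < p_i
    else:
        carrier = rng.uniform(size=n_individuals) < p_comp
    genes = list(prevalences)
    weights = _driver_weights(
        np.array([prevalences[g] for g in genes], dtype=float),
        multi_driver_rate)
    hotspot = {"JAK2": "p.V617F"}

    idx = np.flatnonzero(carrier)
    n_carriers = len(idx)
    multi = rng.uniform(size=n_carriers) < multi_driver_rate
    first = rng.choice(len(genes), size=n_carriers, p=weights)
    owner = [idx, idx[multi]]
    gene_idx = [first]
    # second drivers: redraw until distinct from the first (without
    # replacement within a carrier)
    second = rng.choice(len(genes), size=int(multi.sum()), p=weights)
    clash = second == first[multi]
    while clash.any() and len(genes) > 1:
        second[clash] = rng.choice(len(genes), size=int(clash.sum()), p=weights)
        clash = second == first[multi]
    gene_idx.append(second)
    owner_all = np.concatenate(owner) if n_carriers else np.empty(0, dtype=int)
    gene_all = np.concatenate(gene_idx) if n_carriers else np.empty(0, dtype=int)

    vaf = np.empty(len(gene_all))
    pchange = np.empty(len(gene_all), dtype=object)
    for j, g in enumerate(genes):
        hit = np.flatnonzero(gene_all == j)
        if len(hit) == 0:
            continue
        vaf[hit] = _sample_vaf(g, len(hit), rng, vaf_params)
        if g in hotspot:
            pchange[hit] = hotspot[g]
        else:
            codes = rng.integers(100, 900, size=len(hit))
            pchange[hit] = [f"p.X{c}fs" for c in codes]
    out = pd.DataFrame({
        "sample_id": [sample_ids[i] for i in owner_all],
        "gene": [genes[j] for j in gene_all],
        "protein_change": pchange,
        "vaf": vaf,
    })
    return out.sort_values(["sample_id", "gene"]).reset_index(drop=True)


# ----------------------------------------------------------------- covariates

#: Baseline covariate distributions: age 56.3 (SD 8.1), 44.4% male,
#: predominantly European ancestry, BMI ~27.4, ~45% ever-smokers, ~5% type 2
#: diabetes, ten standard-normal genetic PCs.
COVARIATE_COLUMNS = ["age", "sex", "ancestry", "bmi", "smoker", "t2d"] + \
    [f"pc{k}" for k in range(1, 11)]


def simulate_covariates(n_individuals: int, seed: int,
                        sample_ids: list[str] | None = None) -> pd.DataFrame:
    rng = stream_rng(seed, "covariates")
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n_individuals)]
    df = pd.DataFrame({
        "sample_id": sample_ids,
        "age": rng.normal(56.3, 8.1, n_individuals),
        "sex": (rng.uniform(size=n_individuals) < 0.444).astype(int),
        "ancestry": (rng.uniform(size=n_individuals) < 0.90).astype(int),
        "bmi": rng.normal(27.4, 4.8, n_individuals),
        "smoker": (rng.uniform(size=n_individuals) < 0.45).astype(int),
        "t2d": (rng.uniform(size=n_individuals) < 0.05).astype(int),
    })
    for k in range(1, 11):
        df[f"pc{k}"] = rng.standard_normal(n_individuals)
    return df


# ------------------------------------------------------------------- survival

@dataclass
class SurvivalModelSpec:
    """Generative proportional-hazards model with planted interactions.

    ``baseline_hazard`` is the event rate (per person-year) at linear
    predictor zero.  Log-hazards apply to raw covariate columns, CHIP
    indicator columns, standardized gene scores, and
    ``(chip_variable, gene)`` product terms.  Censoring is the earlier of an
    administrative horizon and an independent exponential dropout time.
    """

    baseline_hazard: float = 0.01
    covariate_log_hazards: dict[str, float] = field(default_factory=dict)
    chip_log_hazards: dict[str, float] = field(default_factory=dict)
    score_log_hazards: dict[str, float] = field(default_factory=dict)
    interaction_log_hazards: dict[tuple[str, str], float] = field(default_factory=dict)
    horizon_years: float = 12.0
    random_censoring_rate: float = 0.004

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline hazard must be positive")
        if self.horizon_years <= 0:
            raise ParameterError("follow-up horizon must be positive")
        if self.random_censoring_rate < 0:
            raise ParameterError("censoring rate must be non-negative")


def linear_predictor(spec: SurvivalModelSpec, covariates: pd.DataFrame,
                     chip_vars: pd.DataFrame | None = None,
                     scores: pd.DataFrame | None = None) -> np.ndarray:
    n = len(covariates)
    lp = np.zeros(n)
    for col, b in spec.covariate_log_hazards.items():
        lp += b * covariates[col].to_numpy(dtype=float)
    if chip_vars is not None:
        for col, b in spec.chip_log_hazards.items():
            lp += b * chip_vars[col].to_numpy(dtype=float)
    if scores is not None:
        for col, b in spec.score_log_hazards.items():
            lp += b * scores[col].to_numpy(dtype=float)
    if chip_vars is not None and scores is not None:
        for (cv, gene), b in spec.interaction_log_hazards.items():
            lp += b * chip_vars[cv].to_numpy(dtype=float) \
                * scores[gene].to_numpy(dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ParameterError("linear predictor is not finite for all individuals")
    return lp


def calibrate_baseline_hazard(spec: SurvivalModelSpec, lp: np.ndarray,
                              target_event_fraction: float) -> float:
    """Baseline rate giving the target marginal event fraction before dropout."""
    lp = np.asarray(lp, dtype=float)
    T = spec.horizon_years

    def frac(rate: float) -> float:
        return float(np.mean(-np.expm1(-rate * np.exp(lp) * T))) - target_event_fraction

    return optimize.brentq(frac, 1e-10, 10.0, xtol=1e-10)


def simulate_survival(covariates: pd.DataFrame, chip_vars: pd.DataFrame | None,
                      scores: pd.DataFrame | None, spec: SurvivalModelSpec,
                      seed: int) -> pd.DataFrame:
    """Follow-up time and event indicator per individual.

    Event times are exponential with rate ``baseline_hazard * exp(lp)``;
    follow-up stops at the earliest of event, random dropout, and the
    administrative horizon.
    """
    rng = stream_rng(seed, "survival")
    lp = linear_predictor(spec, covariates, chip_vars, scores)
    n = len(lp)
    t_event = rng.exponential(1.0, n) / (spec.baseline_hazard * np.exp(lp))
    if spec.random_censoring_rate > 0:
        t_drop = rng.exponential(1.0 / spec.random_censoring_rate, n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, spec.horizon_years)
    follow = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "sample_id": covariates["sample_id"].to_numpy(),
        "follow_time": np.maximum(follow, 1e-8),
        "event": event,
    })


# --------------------------------------------------------------------- traits

HEMATOLOGIC_TRAITS = [
    "wbc", "rbc", "hgb", "hct", "mcv", "mch", "mchc", "rdw", "plt", "mpv",
    "pct", "pdw", "lymph", "mono", "neut", "eos", "baso", "lymph_pct",
    "mono_pct", "neut_pct", "eos_pct", "baso_pct", "ret", "ret_pct", "irf",
    "hls_ret", "hls_ret_pct", "nrbc", "nrbc_pct", "mrv", "mscv",
]
CARDIOMETABOLIC_TRAITS = ["crp", "total_cholesterol", "hdl", "ldl", "triglycerides"]


def simulate_traits(n_individuals: int, seed: int,
                    sample_ids: list[str] | None = None) -> pd.DataFrame:
    """31 hematologic + 5 cardiometabolic quantitative traits.

    Traits are independent log-normal noise (no planted associations); CRP
    carries a ~5% point mass at exactly zero to exercise the +1 offset that
    the log2 transform applies to it downstream.
    """
    rng = stream_rng(seed, "traits")
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n_individuals)]
    df = pd.DataFrame({"sample_id": sample_ids})
    for name in HEMATOLOGIC_TRAITS + CARDIOMETABOLIC_TRAITS:
        df[name] = np.exp(rng.normal(1.0, 0.3, n_individuals))
    zero = rng.uniform(size=n_individuals) < 0.05
    df.loc[zero, "crp"] = 0.0
    return df


# ------------------------------------------------------------- whole cohorts

@dataclass
class CohortConfig:
    """Study conditions of a full synthetic cohort.

    Defaults are the conditions the pipeline's end-to-end checks run under:
    a 10,000-person cohort, three inflammasome-pathway genes with a single
    causal cis variant each, an external eQTL panel of 30,000, composite
    CHIP prevalence 6.2%, a planted composite-CHIP log-hazard of log(1.18),
    and a planted carrier-only AIM2-score interaction of log(1.85) against a
    per-SD non-carrier score effect of log(0.99).
    """

    n_samples: int = 10_000
    n_external: int = 30_000
    n_reference: int = 2_000
    n_validation: int = 4_000
    ld: LdBlockSpec | None = None
    gene_h2: dict[str, float] = field(default_factory=lambda: {
        "AIM2": 0.35, "IL1RAP": 0.15, "IL6R": 0.08})
    causal_effect: float = 1.0
    chip_prevalences: dict[str, float] | None = None
    survival: SurvivalModelSpec | None = None
    target_event_fraction: float = 0.106
    planted_pair: tuple[str, str] = ("has_chip", "AIM2")

    def resolved_ld(self) -> LdBlockSpec:
        if self.ld is not None:
            return self.ld
        genes = list(self.gene_h2)
        spec = LdBlockSpec(n_blocks=max(5, len(genes) + 2), block_size=12)
        pos = spec.positions()
        tss = {}
        for k, g in enumerate(genes):
            # TSS at the centre of block k: its cis window covers that block.
            mid = k * spec.block_size + spec.block_size // 2
            tss[g] = int(pos[mid])
        return replace(spec, gene_tss=tss)

    def architectures(self, spec: LdBlockSpec) -> dict[str, EqtlArchitecture]:
        table = spec.variant_table()
        archs = {}
        for k, (gene, h2) in enumerate(self.gene_h2.items()):
            mid = k * spec.block_size + spec.block_size // 2
            archs[gene] = EqtlArchitecture(
                gene_id=gene,
                causal_variant_ids=[table["variant_id"].iloc[mid]],
                causal_effects=[self.causal_effect],
                h2=h2,
            )
        return archs

    def resolved_survival(self) -> SurvivalModelSpec:
        if self.survival is not None:
            return self.survival
        chip_var, gene = self.planted_pair
        return SurvivalModelSpec(
            covariate_log_hazards={
                "age": 0.07, "sex": 0.40, "bmi": 0.02,
                "smoker": 0.25, "t2d": 0.40,
            },
            chip_log_hazards={chip_var: math.log(1.18)},
            score_log_hazards={gene: math.log(0.99)},
            interaction_log_hazards={(chip_var, gene): math.log(1.85)},
        )


@dataclass
class SyntheticCohort:
    """All generated inputs of one pipeline run."""

    config: CohortConfig
    seed: int
    ld_spec: LdBlockSpec
    architectures: dict[str, EqtlArchitecture]
    reference: DosageMatrix
    genotypes: DosageMatrix
    validation_genotypes: DosageMatrix
    sumstats: pd.DataFrame
    validation_expression: pd.DataFrame
    chip_calls: pd.DataFrame
    phenotypes: pd.DataFrame
    true_genetic_values: pd.DataFrame


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate every input of the pipeline under one master seed.

    The survival outcome is generated against the *true* standardized
    genetic value of each gene (the quantity the predicted expression score
    estimates), so recovery of planted effects through built scores is
    attenuated only by score accuracy.
    """
    config = config or CohortConfig()
    spec = config.resolved_ld()
    archs = config.architectures(spec)
    for arch in archs.values():
        arch.validate_against(spec)

    reference = simulate_ld_panel(spec, 2 * config.n_reference, seed)
    genotypes = simulate_genotypes(spec, config.n_samples, seed, prefix="S")
    validation = simulate_genotypes(spec, config.n_validation, seed,
                                    prefix="V", counter=500)

    sumstats = pd.concat(
        [simulate_external_sumstats(spec, arch, config.n_external, seed, counter=k)
         for k, arch in enumerate(archs.values())],
        ignore_index=True)

    val_expr = pd.DataFrame({"sample_id": validation.sample_ids})
    for k, arch in enumerate(archs.values()):
        val_expr[arch.gene_id] = simulate_expression(
            validation, arch, seed, counter=2000 + k).to_numpy()

    covariates = simulate_covariates(config.n_samples, seed,
                                     sample_ids=list(genotypes.sample_ids))
    chip_calls = simulate_chip_status(
        config.n_samples, prevalences=config.chip_prevalences, seed=seed,
        sample_ids=list(genotypes.sample_ids))

    from .chip import derive_chip_variables  # late import: avoid cycle at module load
    chip_vars = derive_chip_variables(chip_calls, list(genotypes.sample_ids))

    true_g = pd.DataFrame({"sample_id": genotypes.sample_ids})
    for gene, arch in archs.items():
        true_g[gene] = genetic_value(genotypes, arch)

    surv_spec = config.resolved_survival()
    lp_cov = linear_predictor(surv_spec, covariates)
    rate = calibrate_baseline_hazard(surv_spec, lp_cov, config.target_event_fraction)
    surv_spec = replace(surv_spec, baseline_hazard=rate)
    survival = simulate_survival(covariates, chip_vars, true_g, surv_spec, seed)

    traits = simulate_traits(config.n_samples, seed,
                             sample_ids=list(genotypes.sample_ids))
    phenotypes = covariates.merge(survival, on="sample_id").merge(traits, on="sample_id")

    return SyntheticCohort(
        config=config, seed=seed, ld_spec=spec, architectures=archs,
        reference=reference, genotypes=genotypes, validation_genotypes=validation,
        sumstats=sumstats, validation_expression=val_expr, chip_calls=chip_calls,
        phenotypes=phenotypes, true_genetic_values=true_g,
    )
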