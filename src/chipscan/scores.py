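"""Predicted-expression score construction by pruning + thresholding (P+T).

A score for gene *g* is the weighted allele-dosage sum

    PES_i = sum_j beta_j * G_ij,   j in S_clump(r_c^2, w_c), p_j < p_r,

where ``S_clump`` is the set of index variants surviving greedy LD clumping
against a reference panel (squared-correlation threshold ``r_c^2`` inside a
physical window ``w_c`` on both sides of the index) and the indicator keeps
variants whose summary P value is *strictly* below the threshold ``p_r``.
The candidate grid crosses three clumping r^2 levels, five P-value
thresholds, and two window sizes — 30 configurations per gene.

Order of operations: clumping first, thresholding inside the clumped set
(reversing this changes which proxies absorb which hits).  Ties in the
clumping P-value ordering break on ascending (chrom, pos), so results are
invariant to input record order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import DosageMatrix

logger = logging.getLogger(__name__)

CLUMP_R2_GRID = (0.1, 0.01, 0.001)
P_THRESHOLD_GRID = (5e-8, 1e-5, 1e-3, 1e-2, 0.1)
WINDOW_BP_GRID = (250_000, 5_000_000)

#: PRS-CS is not reimplemented here; externally computed posterior-mean
#: weights can be attached through :func:`build_weighted_score`.  Its global
#: shrinkage grid is recorded for provenance.
PRSCS_SHRINKAGE_GRID = (1e-6, 1e-4, 1e-2, 1.0)

AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class MonomorphicVariantError(ValueError):
    """r^2 is undefined for a variant with no dosage variation."""


@dataclass(frozen=True)
class PtConfig:
    """One pruning+thresholding configuration (r_c^2, p_r, w_c)."""

    r2_clump: float
    p_thresh: float
    window_bp: int

    def __post_init__(self) -> None:
        if self.r2_clump not in CLUMP_R2_GRID:
            raise ValueError(f"r2_clump {self.r2_clump} not in grid {CLUMP_R2_GRID}")
        if self.p_thresh not in P_THRESHOLD_GRID:
            raise ValueError(f"p_thresh {self.p_thresh} not in grid {P_THRESHOLD_GRID}")
        if self.window_bp not in WINDOW_BP_GRID:
            raise ValueError(f"window_bp {self.window_bp} not in grid {WINDOW_BP_GRID}")

    @property
    def label(self) -> str:
        return f"r2={self.r2_clump}_p={self.p_thresh}_w={self.window_bp}"


def enumerate_candidate_grid() -> list[PtConfig]:
    """All 30 P+T configurations in fixed (r2, p, window) lexicographic order."""
    return [PtConfig(r2, p, w) for r2, p, w in
            itertools.product(CLUMP_R2_GRID, P_THRESHOLD_GRID, WINDOW_BP_GRID)]


@dataclass
class ClumpResult:
    """Index variants retained by greedy clumping, plus the absorption map."""

    index_variant_ids: list[str]
    removed: dict[str, str] = field(default_factory=dict)  # removed -> index


@dataclass
class ScoreVector:
    """Per-individual predicted expression score for one gene and config."""

    gene_id: str
    config: PtConfig | None
    sample_ids: list[str]
    values: np.ndarray
    n_variants_used: int
    standardized: bool = False
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.sample_ids,
                                                     name="sample_id"),
                         name=self.gene_id)


# ------------------------------------------------------------- harmonization

def harmonize_alleles(sumstats: pd.DataFrame, genotypes: DosageMatrix,
                      drop_ambiguous: bool = True) -> pd.DataFrame:
    """Align summary-statistic effect alleles to the genotype counted allele.

    Variants are matched on ``chrom:pos``.  When the effect allele equals
    the counted allele the record passes through; when the alleles are
    swapped the effect size flips sign; strand-ambiguous (A/T, C/G) variants
    are dropped by default, as are records whose alleles cannot be matched
    or that are absent from the genotypes.  Dropped counts are logged.
    """
    key = sumstats["chrom"].astype(str) + ":" + sumstats["pos"].astype(str)
    if key.duplicated().any():
        dups = key[key.duplicated()].unique().tolist()
        raise ValueError(f"duplicated variant positions in summary stats: {dups[:5]}")
    geno = genotypes.variants.copy()
    gkey = geno["chrom"].astype(str) + ":" + geno["pos"].astype(str)
    if gkey.duplicated().any():
        raise ValueError("duplicated variant positions in genotypes")
    lookup = {k: (r["variant_id"], r["counted_allele"], r["other_allele"])
              for k, (_, r) in zip(gkey, geno.iterrows())}

    rows = []
    n_unmatched = n_ambiguous = n_mismatch = 0
    for (_, rec), k in zip(sumstats.iterrows(), key):
        if k not in lookup:
            n_unmatched += 1
            continue
        ea, oa = str(rec["effect_allele"]), str(rec["other_allele"])
        if drop_ambiguous and frozenset({ea, oa}) in AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        vid, counted, other = lookup[k]
        out = rec.copy()
        out["variant_id"] = vid
        if ea == counted and oa == other:
            pass
        elif ea == other and oa == counted:
            out["beta"] = -rec["beta"]
            out["effect_allele"], out["other_allele"] = counted, other
            if pd.notna(rec.get("eaf", np.nan)):
                out["eaf"] = 1.0 - rec["eaf"]
        else:
            n_mismatch += 1
            continue
        rows.append(out)
    if n_unmatched or n_ambiguous or n_mismatch:
        logger.info("harmonize_alleles dropped %d unmatched, %d strand-ambiguous, "
                    "%d allele-mismatch records", n_unmatched, n_ambiguous, n_mismatch)
    if not rows:
        return sumstats.iloc[0:0].copy()
    return pd.DataFrame(rows).reset_index(drop=True)


# ----------------------------------------------------------------------- LD

def ld_r2(reference: DosageMatrix, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of two variants' dosages in the reference."""
    a = reference.dosage(variant_a)
    b = reference.dosage(variant_b)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(set(a)) < 2 or len(set(b)) < 2:
        raise MonomorphicVariantError(
            f"r^2 undefined for monomorphic pair ({variant_a}, {variant_b})")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_against(reference: DosageMatrix, index_col: int,
                other_cols: np.ndarray) -> np.ndarray:
    """Vectorized r^2 of one column against several (NaN-free fast path)."""
    X = reference.values
    x = X[:, index_col]
    Y = X[:, other_cols]
    if np.isnan(x).any() or np.isnan(Y).any():
        out = np.empty(len(other_cols))
        for i, c in enumerate(other_cols):
            y = X[:, c]
            ok = ~(np.isnan(x) | np.isnan(y))
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                out[i] = 0.0
            else:
                out[i] = np.corrcoef(xs, ys)[0, 1] ** 2
        return out
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = float(xc @ xc)
    sy = (Yc ** 2).sum(axis=0)
    if sx == 0:
        return np.zeros(len(other_cols))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (xc @ Yc) ** 2 / (sx * sy)
    return np.where(sy > 0, r2, 0.0)  # monomorphic partner: treat as r^2 = 0


# ------------------------------------------------------------------ clumping

def clump(sumstats: pd.DataFrame, reference: DosageMatrix, r2_clump: float,
          window_bp: int, missing_reference: str = "drop") -> ClumpResult:
    """Greedy P-value-ordered LD clumping.

    Repeatedly promote the remaining record with the smallest P value to
    index status (ties break on ascending chrom, pos) and absorb every
    remaining record within ``window_bp`` of it (inclusive, both sides)
    whose reference r^2 with the index is >= ``r2_clump``.  Records absent
    from the reference are dropped (default) or kept unclumped.
    """
    df = sumstats.copy()
    if df["pvalue"].isna().any() or not np.all(np.isfinite(df["pvalue"].astype(float))):
        raise ValueError("clump requires finite P values for all records")
    in_ref = df["variant_id"].isin(reference.variants["variant_id"]).to_numpy()
    kept_unclumped: list[str] = []
    if not in_ref.all():
        absent = df.loc[~in_ref, "variant_id"].tolist()
        if missing_reference == "drop":
            logger.info("clump dropped %d variants absent from reference", len(absent))
            df = df.loc[in_ref]
        elif missing_reference == "keep":
            logger.warning("clump keeping %d unclumped variants absent from "
                           "reference", len(absent))
            kept_unclumped = absent
            df = df.loc[in_ref]
        else:
            raise ValueError("missing_reference must be 'drop' or 'keep'")
    # order on log-space P when supplied (biobank-scale statistics underflow
    # the linear-scale P, which would turn the ordering into a position tie)
    sort_p = "log10_pvalue" if "log10_pvalue" in df.columns \
        and df["log10_pvalue"].notna().all() else "pvalue"
    df = df.sort_values([sort_p, "chrom", "pos"],
                        kind="mergesort").reset_index(drop=True)
    vids = df["variant_id"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    chrom = df["chrom"].astype(str).to_numpy()
    cols = np.array([reference.column_index(v) for v in vids], dtype=int) \
        if len(vids) else np.empty(0, dtype=int)

    alive = np.ones(len(df), dtype=bool)
    index_ids: list[str] = []
    removed: dict[str, str] = {}
    for i in range(len(df)):
        if not alive[i]:
            continue
        alive[i] = False
        index_ids.append(vids[i])
        cand = np.flatnonzero(alive & (chrom == chrom[i])
                              & (np.abs(pos - pos[i]) <= window_bp))
        if len(cand) == 0:
            continue
        r2 = _r2_against(reference, cols[i], cols[cand])
        hit = cand[r2 >= r2_clump]
        for j in hit:
            removed[vids[j]] = vids[i]
            alive[j] = False
    index_ids.extend(kept_unclumped)
    return ClumpResult(index_variant_ids=index_ids, removed=removed)


# -------------------------------------------------------------------- scoring

def build_pt_score(genotypes: DosageMatrix, sumstats: pd.DataFrame,
                   clumped: ClumpResult, p_thresh: float,
                   config: PtConfig | None = None) -> ScoreVector:
    """Evaluate the P+T weighted dosage sum for every individual.

    Keeps clumped index variants with ``pvalue < p_thresh`` (strict), mean-
    imputes missing dosages per variant from the cohort, and returns an
    all-zero score flagged degenerate when no variant passes.
    """
    gene_id = str(sumstats["gene_id"].iloc[0]) if len(sumstats) else ""
    idx_set = set(clumped.index_variant_ids)
    sel = sumstats[sumstats["variant_id"].isin(idx_set)
                   & (sumstats["pvalue"] < p_thresh)]
    if len(sel) == 0:
        return ScoreVector(gene_id=gene_id, config=config,
                           sample_ids=list(genotypes.sample_ids),
                           values=np.zeros(genotypes.n_samples),
                           n_variants_used=0, degenerate=True)
    cols = [genotypes.column_index(v) for v in sel["variant_id"]]
    G = genotypes.values[:, cols].copy()
    if np.isnan(G).any():
        means = np.nanmean(G, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        nan_r, nan_c = np.nonzero(np.isnan(G))
        G[nan_r, nan_c] = means[nan_c]
    beta = sel["beta"].to_numpy(dtype=float)
    return ScoreVector(gene_id=gene_id, config=config,
                       sample_ids=list(genotypes.sample_ids),
                       values=G @ beta, n_variants_used=len(sel))


def build_weighted_score(genotypes: DosageMatrix, weights: pd.DataFrame,
                         gene_id: str, method_id: str = "external") -> ScoreVector:
    """Plug-in scorer for externally computed per-variant weights.

    Accepts posterior-mean weights from a shrinkage method (e.g. PRS-CS
    over its shrinkage grid :data:`PRSCS_SHRINKAGE_GRID`) as a DataFrame
    with ``variant_id`` and ``weight`` columns, already harmonized to the
    genotype counted alleles.
    """
    present = weights[weights["variant_id"].isin(genotypes.variants["variant_id"])]
    if len(present) == 0:
        return ScoreVector(gene_id=gene_id, config=None,
                           sample_ids=list(genotypes.sample_ids),
                           values=np.zeros(genotypes.n_samples),
                           n_variants_used=0, degenerate=True)
    cols = [genotypes.column_index(v) for v in present["variant_id"]]
    G = np.nan_to_num(genotypes.values[:, cols],
                      nan=np.nanmean(genotypes.values[:, cols]))
    return ScoreVector(gene_id=gene_id, config=None,
                       sample_ids=list(genotypes.sample_ids),
                       values=G @ present["weight"].to_numpy(dtype=float),
                       n_variants_used=len(present))


def standardize_score(score: ScoreVector,
                      population: list[str] | None = None) -> ScoreVector:
    """Zero-mean unit-variance rescaling on the stated population.

    Uses the population SD convention (denominator n).  A constant score is
    degenerate: values become all zero and the flag propagates.  The
    standardizing population may be a sample subset (e.g. one ancestry
    stratum); the transform is then applied to all samples.
    """
    if population is not None and len(population) == 0:
        raise ValueError("standardization population is empty")
    pop = set(population) if population is not None else None
    mask = np.array([s in pop for s in score.sample_ids]) if pop is not None \
        else np.ones(len(score.sample_ids), dtype=bool)
    if not mask.any():
        raise ValueError("standardization population matches no samples")
    vals = score.values[mask]
    vals = vals[~np.isnan(vals)]
    sd = vals.std()  # population convention, ddof=0
    if score.degenerate or sd == 0:
        return replace(score, values=np.zeros_like(score.values),
                       standardized=True, degenerate=True)
    return replace(score, values=(score.values - vals.mean()) / sd,
                   standardized=True)


def build_grid_scores(genotypes: DosageMatrix, sumstats: pd.DataFrame,
                      reference: DosageMatrix,
                      grid: list[PtConfig] | None = None,
                      standardize: bool = True) -> list[ScoreVector]:
    """All candidate scores of one gene across the P+T grid.

    Clumping depends only on (r2, window), so the six clump results are
    shared across the five P thresholds.
    """
    grid = grid if grid is not None else enumerate_candidate_grid()
    aligned = harmonize_alleles(sumstats, genotypes)
    aligned = aligned.dropna(subset=["beta", "pvalue"])
    clump_cache: dict[tuple[float, int], ClumpResult] = {}
    out = []
    for cfg in grid:
        ck = (cfg.r2_clump, cfg.window_bp)
        if ck not in clump_cache:
            clump_cache[ck] = clump(aligned, reference, cfg.r2_clump, cfg.window_bp)
        sv = build_pt_score(genotypes, aligned, clump_cache[ck],
                            cfg.p_thresh, config=cfg)
        out.append(standardize_score(sv) if standardize else sv)
    return out
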