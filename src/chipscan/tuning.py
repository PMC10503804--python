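"""Score tuning: pick the best candidate per gene by variance explained.

Candidates are evaluated against measured expression in one or more
validation cohorts (whole-blood-like and PBMC-like).  Expression is first
residualized on covariates (age, sex, PCs by default) and re-standardized;
r^2 is then the squared Pearson correlation between score and adjusted
expression.  The best candidate is the argmax over configs x cohorts, ties
breaking on grid enumeration order, and a gene is retained for the modifier
scan only when its best r^2 strictly exceeds 1%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scores import PtConfig, ScoreVector

logger = logging.getLogger(__name__)

RETENTION_R2 = 0.01      # strict ">" retention rule
MIN_OVERLAP = 30         # stability floor for reporting an r^2


@dataclass
class TuningResult:
    gene_id: str
    table: pd.DataFrame              # columns: config, cohort, r2, degenerate
    best_config: PtConfig | None
    best_cohort: str | None
    best_r2: float
    retained: bool
    reason: str = ""


def residualize_expression(expression: pd.Series,
                           covariates: pd.DataFrame | None) -> pd.Series:
    """Residuals of a linear covariate adjustment, re-standardized to SD 1.

    With no covariates the expression is simply standardized.  Collinear
    covariate columns are handled by a minimum-norm least-squares fit (a
    warning is emitted when the design is rank-deficient).  If the
    covariates absorb essentially all variance the result is degenerate and
    returned as all zeros.
    """
    y = expression.to_numpy(dtype=float)
    if covariates is not None and len(covariates.columns) > 0:
        X = covariates.to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(X)), X])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn("rank-deficient covariates in expression adjustment; "
                          "collinear columns effectively dropped", stacklevel=2)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    else:
        resid = y - y.mean()
    sd = resid.std()
    if sd < 1e-10:
        logger.warning("expression fully explained by covariates for %s; "
                       "degenerate residuals", expression.name)
        return pd.Series(np.zeros_like(resid), index=expression.index,
                         name=expression.name)
    return pd.Series(resid / sd, index=expression.index, name=expression.name)


def evaluate_r2(score: ScoreVector, adjusted_expression: pd.Series) -> float:
    """Proportion of adjusted expression variance explained by the score.

    Squared Pearson correlation over overlapping non-missing samples;
    degenerate (constant) scores score 0.  Requires at least
    :data:`MIN_OVERLAP` overlapping samples.
    """
    s = score.as_series()
    joined = pd.concat([s, adjusted_expression], axis=1, join="inner").dropna()
    if len(joined) < MIN_OVERLAP:
        raise ValueError(f"only {len(joined)} overlapping samples "
                         f"(need >= {MIN_OVERLAP})")
    a = joined.iloc[:, 0].to_numpy()
    b = joined.iloc[:, 1].to_numpy()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def select_best_score(candidates: list[ScoreVector],
                      validation_sets: dict[str, tuple[pd.Series, pd.DataFrame | None]],
                      ) -> TuningResult:
    """Evaluate every candidate in every validation cohort; keep the argmax.

    ``validation_sets`` maps a cohort label to ``(expression, covariates)``.
    Ties on r^2 break toward the earlier candidate in grid order and the
    earlier cohort.  ``retained`` is ``best_r2 > 0.01`` (strict).
    """
    if not candidates:
        raise ValueError("no candidate scores supplied")
    if not validation_sets:
        raise ValueError("no validation sets supplied")
    gene_id = candidates[0].gene_id
    adjusted = {cohort: residualize_expression(expr, cov)
                for cohort, (expr, cov) in validation_sets.items()}
    rows = []
    best = (None, None, -np.inf)
    for ci, cand in enumerate(candidates):
        for cohort, adj in adjusted.items():
            r2 = 0.0 if cand.degenerate else evaluate_r2(cand, adj)
            rows.append({"config": cand.config.label if cand.config else f"cand{ci}",
                         "cohort": cohort, "r2": r2,
                         "degenerate": cand.degenerate})
            if r2 > best[2]:
                best = (ci, cohort, r2)
    table = pd.DataFrame(rows)
    if all(c.degenerate for c in candidates):
        return TuningResult(gene_id=gene_id, table=table, best_config=None,
                            best_cohort=None, best_r2=0.0, retained=False,
                            reason="all candidates degenerate")
    ci, cohort, r2 = best
    return TuningResult(gene_id=gene_id, table=table,
                        best_config=candidates[ci].config, best_cohort=cohort,
                        best_r2=float(r2), retained=bool(r2 > RETENTION_R2))


def tune_gene(candidates: list[ScoreVector],
              validation_sets: dict[str, tuple[pd.Series, pd.DataFrame | None]],
              ) -> TuningResult:
    """Alias of :func:`select_best_score` (pipeline-facing name)."""
    return select_best_score(candidates, validation_sets)
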