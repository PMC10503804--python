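"""Vectorized Cox proportional-hazards fitting (Efron ties).

A Newton–Raphson maximizer of the partial likelihood, written directly on
numpy arrays so that the Monte-Carlo calibration loops of the modifier scan
(thousands of fits on cohorts of 10^4–10^5 rows) run in milliseconds per
fit.  Efron's approximation handles tied event times; with no ties it
coincides with the exact partial likelihood.  Standard errors come from the
inverse of the observed information, giving Wald z statistics, two-tailed P
values, and 95% CIs per coefficient.

The test suite cross-checks coefficients and standard errors against
``lifelines.CoxPHFitter`` on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass
class CoxFit:
    """Result of one partial-likelihood fit."""

    terms: list[str]
    coef: np.ndarray           # log hazard ratios
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_iter: int

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.coef - q * self.se, self.coef + q * self.se])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        with np.errstate(over="ignore"):  # near-separation: CI bounds may be inf
            return pd.DataFrame({
                "term": self.terms,
                "coef": self.coef,
                "hr": np.exp(self.coef),
                "se": self.se,
                "z": self.z,
                "pvalue": self.pvalues,
                "ci_low": np.exp(ci[:, 0]),
                "ci_high": np.exp(ci[:, 1]),
            }).set_index("term")


class CoxConvergenceError(RuntimeError):
    pass


@dataclass
class _Prepared:
    """Sorted design and tied-event bookkeeping (independent of beta)."""

    Xs: np.ndarray        # design in descending-time order
    ev_pos: np.ndarray    # sorted-order positions of event rows
    ev_group: np.ndarray  # event-time group id per event row
    ev_frac: np.ndarray   # Efron fraction l/d per event row
    seg_ends: np.ndarray  # risk-set prefix length per group (ascending)
    n_groups: int


def _prepare(time, event, X) -> _Prepared:
    """Sort descending by time (events last among ties, so the cumulative
    prefix at a group end covers the whole risk set {time >= t})."""
    order = np.lexsort((event, -time))
    t_s = time[order]
    e_s = event[order]
    ev_pos = np.flatnonzero(e_s)
    ev_times = t_s[ev_pos]
    new_group = np.ones(len(ev_pos), dtype=bool)
    new_group[1:] = np.diff(ev_times) != 0
    ev_group = np.cumsum(new_group) - 1
    n_groups = int(ev_group[-1]) + 1 if len(ev_pos) else 0
    # within-group rank -> Efron fraction l / d
    d = np.bincount(ev_group, minlength=n_groups)
    group_start = np.concatenate([[0], np.cumsum(d)[:-1]])
    rank = np.arange(len(ev_pos)) - group_start[ev_group]
    ev_frac = rank / d[ev_group]
    # risk-set prefix per group ends at the last (tied) event row
    seg_ends = ev_pos[group_start + d - 1] + 1
    return _Prepared(Xs=X[order], ev_pos=ev_pos, ev_group=ev_group,
                     ev_frac=ev_frac, seg_ends=seg_ends, n_groups=n_groups)


def _efron_quantities(beta, prep: _Prepared):
    """Log-likelihood, gradient, observed information (Efron ties).

    Risk sets are nested prefixes of the descending-time order, so sums of
    ``w_j x_j x_j^T / den`` over all (group, Efron-term) pairs collapse into
    one weighted Gram matrix with per-row suffix-summed weights.
    """
    Xs = prep.Xs
    n, p = Xs.shape
    G = prep.n_groups
    # near-separation iterates can overflow transiently; the caller checks
    # finiteness of (ll, grad, info) and flags non-convergence
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return _efron_core(beta, prep, Xs, n, p, G)


def _efron_core(beta, prep, Xs, n, p, G):
    eta = Xs @ beta
    eta = eta - eta.max()  # scale cancels in the partial likelihood
    w = np.exp(eta)
    cw = np.cumsum(w)
    cXw = np.cumsum(Xs * w[:, None], axis=0)
    S0 = cw[prep.seg_ends - 1]                      # (G,)
    S1 = cXw[prep.seg_ends - 1]                     # (G, p)

    wD = w[prep.ev_pos]
    XD = Xs[prep.ev_pos]
    sw = np.bincount(prep.ev_group, weights=wD, minlength=G)
    s1D = np.zeros((G, p))
    np.add.at(s1D, prep.ev_group, XD * wD[:, None])

    f = prep.ev_frac
    den = S0[prep.ev_group] - f * sw[prep.ev_group]  # one Efron term per event
    inv = 1.0 / den
    c0 = np.bincount(prep.ev_group, weights=inv, minlength=G)
    cf = np.bincount(prep.ev_group, weights=f * inv, minlength=G)
    inv2 = inv * inv
    d0 = np.bincount(prep.ev_group, weights=inv2, minlength=G)
    d1 = np.bincount(prep.ev_group, weights=f * inv2, minlength=G)
    d2 = np.bincount(prep.ev_group, weights=f * f * inv2, minlength=G)

    ll = float(eta[prep.ev_pos].sum() - np.log(den).sum())
    grad = XD.sum(axis=0) - (S1 * c0[:, None]).sum(axis=0) \
        + (s1D * cf[:, None]).sum(axis=0)

    # suffix sum of c0 over groups whose risk set contains each sorted row
    k = np.searchsorted(prep.seg_ends, np.arange(n), side="right")
    csum = np.concatenate([[0.0], np.cumsum(c0)])
    B = csum[G] - csum[k]                            # (n,)
    term_a = Xs.T @ (Xs * (w * B)[:, None])
    term_b = XD.T @ (XD * (wD * cf[prep.ev_group])[:, None])
    term_c = S1.T @ (S1 * d0[:, None])
    term_d = S1.T @ (s1D * d1[:, None])
    term_e = s1D.T @ (s1D * d2[:, None])
    info = term_a - term_b - term_c + term_d + term_d.T - term_e
    return ll, grad, info


def fit_cox_fast(time, event, X: pd.DataFrame | np.ndarray,
                 terms: list[str] | None = None, max_iter: int = 60,
                 tol: float = 1e-9) -> CoxFit:
    """Newton–Raphson Cox fit with step-halving.

    Parameters are raw arrays; use :func:`chipscan.scan.fit_cox` for the
    DataFrame-level interface with complete-case filtering and guards.
    """
    if isinstance(X, pd.DataFrame):
        terms = terms or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        terms = terms or [f"x{i}" for i in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    n_events = int(event.sum())
    if n_events == 0:
        raise CoxConvergenceError("no events in the analysis set")
    # centering improves conditioning; leaves coefficients unchanged
    center = X.mean(axis=0)
    Xc = X - center
    prep = _prepare(time, event, Xc)

    beta = np.zeros(p)
    ll, grad, info = _efron_quantities(beta, prep)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(info))):
            converged = False  # separation: likelihood unbounded along a direction
            break
        try:
            step = linalg.solve(info, grad, assume_a="pos")
        except (linalg.LinAlgError, ValueError):
            step = np.linalg.pinv(np.nan_to_num(info)) @ grad
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _efron_quantities(cand, prep)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        delta = ll_new - ll
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(grad)) < 1e-6 or abs(delta) < tol:
            converged = True
            break
    try:
        cov = linalg.inv(info)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)):
            converged = False
            se = np.where(np.isfinite(se), se, np.inf)
    except (linalg.LinAlgError, ValueError):
        converged = False
        se = np.full(p, np.inf)
    return CoxFit(terms=terms, coef=beta, se=se, loglik=float(ll), n=n,
                  n_events=n_events, converged=converged, n_iter=it)
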