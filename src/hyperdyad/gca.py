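"""Directional coupling via bivariate Granger causality.

A vector autoregression (VAR) with intercept is fit by least squares to
the two members' task-period HbO at the surviving channel pair; the lag
order is chosen by the Bayesian information criterion (BIC) evaluated on
a common effective sample.  Granger causality in each direction is the
log ratio of restricted to full maximum-likelihood residual variances;
with only two series the pairwise conditional measure reduces to
ordinary bivariate G-causality (there is no conditioning set).  The
direction x block contrast in couples is a fully-within 2x2
repeated-measures ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .stats import FTable, rm_anova_2x2, t_test

__all__ = [
    "VARFit",
    "fit_var",
    "bic_order",
    "granger_pair",
    "cohort_granger",
    "direction_test",
]


@dataclass
class VARFit:
    order: int
    intercept: np.ndarray        # (dim,)
    coefs: np.ndarray            # (order, dim, dim); coefs[l][i, j]: x_j(t-l-1) -> x_i(t)
    resid_cov: np.ndarray        # ML covariance (divide by effective n)
    residuals: np.ndarray        # (n_eff, dim)
    loglik: float
    n_obs: int                   # effective sample size


def _lag_design(x: np.ndarray, order: int, start: int | None = None):
    """Design matrix of lagged values with intercept.  ``start`` fixes the
    first usable time index (>= order) so different orders can share an
    effective sample."""
    n, dim = x.shape
    start = order if start is None else start
    rows = n - start
    cols = [np.ones(rows)]
    for lag in range(1, order + 1):
        cols.append(x[start - lag: n - lag])
    design = np.column_stack(cols)
    return design, x[start:]


def fit_var(series_2d: np.ndarray, order: int, *, start: int | None = None) -> VARFit:
    """Least-squares VAR(order) with intercept on a (n_t, dim) series."""
    x = np.asarray(series_2d, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be 2-D (time x dim)")
    n, dim = x.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= (start or order) + dim * order + 1:
        raise ValueError("series too short for the requested order")
    design, y = _lag_design(x, order, start)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient VAR design (constant or duplicated series?)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    n_eff = len(y)
    cov = resid.T @ resid / n_eff
    coefs = beta[1:].reshape(order, dim, dim).transpose(0, 2, 1)
    sign, logdet = np.linalg.slogdet(cov)
    loglik = -0.5 * n_eff * (dim * (1 + np.log(2 * np.pi)) + logdet) \
        if sign > 0 else -np.inf
    return VARFit(order, beta[0], coefs, cov, resid, float(loglik), n_eff)


def bic_order(series_2d: np.ndarray, max_order: int = 8) -> int:
    """BIC order selection on a common effective sample: BIC(m) =
    n * ln det(resid cov) + k * ln n with k = dim^2 * m + dim estimated
    parameters; ties go to the smaller order."""
    x = np.asarray(series_2d, dtype=float)
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    dim = x.shape[1]
    best, best_bic = 1, np.inf
    for order in range(1, max_order + 1):
        fit = fit_var(x, order, start=max_order)
        n = fit.n_obs
        sign, logdet = np.linalg.slogdet(fit.resid_cov)
        if sign <= 0:
            continue
        k = dim * dim * order + dim
        bic = n * logdet + k * np.log(n)
        if bic < best_bic - 1e-12:
            best, best_bic = order, bic
    return best


def granger_pair(x: np.ndarray, y: np.ndarray, order: int):
    """Bivariate Granger causality in both directions from one VAR fit:
    gc_x->y = ln(sigma2_restricted / sigma2_full) for y's equation, where
    the restricted model omits x's lags (and vice versa).  Residual
    variances are maximum likelihood (divide by effective n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    data = np.column_stack([x, y])
    full = fit_var(data, order)
    var_full = np.diag(full.resid_cov)  # [var_x_eq, var_y_eq]
    if np.any(var_full <= 0):
        raise FloatingPointError("non-positive full-model residual variance")

    def restricted_var(target_col, omit_col):
        design, ytar = _lag_design(data, order)
        keep = [0] + [1 + lag * 2 + omit_col_complement
                      for lag in range(order)
                      for omit_col_complement in range(2)
                      if omit_col_complement != omit_col]
        d = design[:, keep]
        beta, *_ = np.linalg.lstsq(d, ytar[:, target_col], rcond=None)
        resid = ytar[:, target_col] - d @ beta
        return float(resid @ resid / len(resid))

    gc_x_to_y = np.log(restricted_var(1, 0) / var_full[1])
    gc_y_to_x = np.log(restricted_var(0, 1) / var_full[0])
    return float(gc_x_to_y), float(gc_y_to_x)


def cohort_granger(sessions, hbo_pairs, target_pair, config: AnalysisConfig,
                   *, order: int | str = "bic", groups=("couple",)) -> pd.DataFrame:
    """Per-dyad, per-block G-causality at the target channel pair on the
    preprocessed broadband HbO (each block's samples form one series).
    ``order='bic'`` selects one common order: the modal BIC choice
    across dyads and blocks.  Returns a DataFrame (dyad_id, group,
    block, gc_m_to_f, gc_f_to_m, order)."""
    ch_m, ch_f = target_pair
    fs = config.downsample_hz
    segments = []
    for sess, (hm, hf) in zip(sessions, hbo_pairs):
        if groups and sess.group not in groups:
            continue
        n_t = hm.hbo.shape[1]
        for b in (1, 2):
            mask = sess.timeline.sample_mask(fs, n_t, "block", b)
            segments.append((sess.dyad_id, sess.group, b,
                             hm.hbo[ch_m - 1, mask], hf.hbo[ch_f - 1, mask]))
    if not segments:
        raise ValueError("no dyads in the requested groups")
    if order == "bic":
        picks = [bic_order(np.column_stack([xm, xf]), config.gc_max_order)
                 for (_, _, _, xm, xf) in segments]
        chosen = int(np.bincount(picks).argmax())
    else:
        chosen = int(order)
    rows = []
    for (dyad_id, group, b, xm, xf) in segments:
        gc_mf, gc_fm = granger_pair(xm, xf, chosen)
        rows.append((dyad_id, group, b, gc_mf, gc_fm, chosen))
    return pd.DataFrame(rows, columns=["dyad_id", "group", "block",
                                       "gc_m_to_f", "gc_f_to_m", "order"])


def direction_test(gc_results: pd.DataFrame):
    """Direction x block repeated-measures ANOVA within dyads, plus
    paired direction contrasts per block (the follow-up report shape).
    Returns (FTable, simple-effects DataFrame)."""
    wide = gc_results.pivot_table(index="dyad_id", columns="block",
                                  values=["gc_m_to_f", "gc_f_to_m"])
    wide = wide.dropna()
    if len(wide) < 2:
        raise ValueError("direction test needs at least 2 complete dyads")
    y11 = wide[("gc_m_to_f", 1)].to_numpy()   # direction M->F, block 1
    y12 = wide[("gc_m_to_f", 2)].to_numpy()
    y21 = wide[("gc_f_to_m", 1)].to_numpy()
    y22 = wide[("gc_f_to_m", 2)].to_numpy()
    ftab = rm_anova_2x2(y11, y12, y21, y22, names=("direction", "block"))
    rows = []
    for b, (a, c) in ((1, (y11, y21)), (2, (y12, y22))):
        r = t_test(a, c, mode="paired")
        rows.append((b, "m_to_f vs f_to_m", r.t, r.df, r.p, r.cohens_d))
    simple = pd.DataFrame(rows, columns=["block", "contrast", "t", "df", "p",
                                         "cohens_d"])
    return ftab, simple
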