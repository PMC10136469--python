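"""Statistical engine: t-tests with effect sizes, Benjamini-Hochberg FDR,
a mixed-design (between x within) ANCOVA for two-level within factors,
a 2x2 fully-within repeated-measures ANOVA, and simple effects.

The mixed ANCOVA uses the exact difference-score GLM formulation for a
two-level within factor: the within main effect and the between x within
interaction are tested on per-unit difference scores (level2 - level1)
with covariates adjusted, and the between main effect on per-unit means.
On balanced covariate-free designs this reproduces the classical mixed
ANOVA F ratios exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "TTestResult",
    "FTable",
    "t_test",
    "fdr_bh",
    "mixed_ancova",
    "rm_anova_2x2",
    "simple_effects",
]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    degenerate: bool = False  # zero-variance input handled by convention


def t_test(x, y, mode: str = "independent") -> TTestResult:
    """Two-sided t-test.  ``paired`` d = mean(diff)/sd(diff); independent
    d uses the pooled sd.  Zero variance with zero mean difference gives
    t = 0, p = 1; zero variance with a nonzero difference gives an
    infinite t reported as p -> 0 with the ``degenerate`` flag set."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "paired":
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        n = len(d)
        if n < 2:
            raise ValueError("need at least 2 pairs")
        md, sd = d.mean(), d.std(ddof=1)
        df = n - 1
        if sd == 0:
            if md == 0:
                return TTestResult(0.0, df, 1.0, 0.0, degenerate=True)
            return TTestResult(np.inf if md > 0 else -np.inf, df, 0.0,
                               np.inf if md > 0 else -np.inf, degenerate=True)
        t = md / (sd / np.sqrt(n))
        dval = md / sd
    elif mode == "independent":
        n1, n2 = len(x), len(y)
        if min(n1, n2) < 2:
            raise ValueError("need at least 2 observations per sample")
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        diff = x.mean() - y.mean()
        if sp2 == 0:
            if diff == 0:
                return TTestResult(0.0, df, 1.0, 0.0, degenerate=True)
            return TTestResult(np.inf if diff > 0 else -np.inf, df, 0.0,
                               np.inf if diff > 0 else -np.inf, degenerate=True)
        t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        dval = diff / np.sqrt(sp2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = 2 * spstats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), float(dval))


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up.  Returns (reject mask, adjusted p).
    NaN entries are ignored (never rejected, adjusted p = NaN)."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    adj = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return mask, adj
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    # adjusted p: monotone backward-cumulative minimum of p * m / rank
    raw = ranked * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    adj_sorted = np.clip(adj_sorted, 0, 1)
    below = np.nonzero(ranked <= np.arange(1, m + 1) / m * q)[0]
    rej_sorted = np.zeros(m, dtype=bool)
    if below.size:
        rej_sorted[: below[-1] + 1] = True
    rej = np.empty(m, dtype=bool)
    rej[order] = rej_sorted
    av = np.empty(m)
    av[order] = adj_sorted
    mask[valid] = rej
    adj[valid] = av
    return mask, adj


# ---------------------------------------------------------------------------
# linear-model helpers

def _ols_effect_f(y, x_full, drop_col):
    """F test for a single column of an OLS design via full-vs-reduced
    residual sums of squares.  Returns (F, df_num, df_den, p, eta_p2)."""
    n, p_full = x_full.shape
    x_red = np.delete(x_full, drop_col, axis=1)
    beta_f, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    beta_r, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    rss_f = float(np.sum((y - x_full @ beta_f) ** 2))
    rss_r = float(np.sum((y - x_red @ beta_r) ** 2))
    df_den = n - p_full
    if df_den <= 0:
        raise ValueError("not enough units for the requested model")
    ss_eff = max(rss_r - rss_f, 0.0)
    if rss_f <= 1e-300:
        f = 0.0 if ss_eff <= 1e-300 else np.inf
    else:
        f = (ss_eff / 1) / (rss_f / df_den)
    p = float(spstats.f.sf(f, 1, df_den)) if np.isfinite(f) else 0.0
    eta = ss_eff / (ss_eff + rss_f) if (ss_eff + rss_f) > 0 else 0.0
    return float(f), 1, df_den, p, float(eta)


def _check_collinearity(x, tol=1e10):
    s = np.linalg.svd(x, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > tol:
        raise ValueError("design matrix is collinear "
                         "(a covariate may be constant or confounded with group)")


@dataclass
class FTable:
    """Per-effect F statistics as a DataFrame with columns
    effect, F, df_num, df_den, p, eta_p2."""

    table: pd.DataFrame

    def row(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]


def mixed_ancova(table: pd.DataFrame, dv: str, between: str, within: str,
                 unit: str = "unit", covariates: tuple[str, ...] = ()) -> FTable:
    """Mixed-design ANCOVA for a two-level within factor with a two-level
    between factor and numeric covariates (constant within unit).

    ``table`` is long format: one row per unit x within level.
    """
    levels_w = sorted(table[within].unique())
    if len(levels_w) != 2:
        raise ValueError("the within factor must have exactly 2 levels")
    levels_b = sorted(table[between].unique())
    if len(levels_b) != 2:
        raise ValueError("the between factor must have exactly 2 levels")
    wide = table.pivot_table(index=unit, columns=within, values=dv)
    wide = wide.dropna()
    meta = table.drop_duplicates(unit).set_index(unit).loc[wide.index]
    grp = np.where(meta[between] == levels_b[0], 1.0, -1.0)
    covs = np.column_stack([meta[c].to_numpy(float) for c in covariates]) \
        if covariates else np.empty((len(wide), 0))
    covs = covs - covs.mean(axis=0, keepdims=True) if covs.size else covs

    y1 = wide[levels_w[0]].to_numpy(float)
    y2 = wide[levels_w[1]].to_numpy(float)
    diff = y2 - y1
    mean = (y1 + y2) / 2.0

    x = np.column_stack([np.ones(len(diff)), grp, covs])
    _check_collinearity(x)
    rows = []
    f, dn, dd, p, eta = _ols_effect_f(mean, x, 1)
    rows.append((between, f, dn, dd, p, eta))
    f, dn, dd, p, eta = _ols_effect_f(diff, x, 0)   # within main effect
    rows.append((within, f, dn, dd, p, eta))
    f, dn, dd, p, eta = _ols_effect_f(diff, x, 1)   # interaction
    rows.append((f"{between}:{within}", f, dn, dd, p, eta))
    return FTable(pd.DataFrame(rows, columns=["effect", "F", "df_num",
                                              "df_den", "p", "eta_p2"]))


def rm_anova_2x2(y11, y12, y21, y22, names=("factor_a", "factor_b")) -> FTable:
    """Fully-within 2x2 repeated-measures ANOVA via contrast t-tests
    (each effect F(1, n-1) = t^2 on the per-unit contrast score).
    Arguments are per-unit arrays: y[a-level][b-level]."""
    y11, y12, y21, y22 = (np.asarray(a, float) for a in (y11, y12, y21, y22))
    n = len(y11)
    rows = []
    contrasts = {
        names[0]: (y21 + y22) - (y11 + y12),
        names[1]: (y12 + y22) - (y11 + y21),
        f"{names[0]}:{names[1]}": (y22 - y21) - (y12 - y11),
    }
    for effect, c in contrasts.items():
        c = c / 2.0
        sd = c.std(ddof=1)
        if sd == 0:
            f, p, eta = (0.0, 1.0, 0.0) if np.isclose(c.mean(), 0) else (np.inf, 0.0, 1.0)
        else:
            t = c.mean() / (sd / np.sqrt(n))
            f = t**2
            p = 2 * spstats.t.sf(abs(t), n - 1)
            eta = f / (f + (n - 1))
        rows.append((effect, float(f), 1, n - 1, float(p), float(eta)))
    return FTable(pd.DataFrame(rows, columns=["effect", "F", "df_num",
                                              "df_den", "p", "eta_p2"]))


def simple_effects(table: pd.DataFrame, dv: str, between: str, within: str,
                   unit: str = "unit") -> pd.DataFrame:
    """Follow-up t-tests after an interaction: paired t across within
    levels inside each between level, and independent t across between
    levels inside each within level."""
    levels_b = sorted(table[between].unique())
    levels_w = sorted(table[within].unique())
    wide = table.pivot_table(index=unit, columns=within, values=dv).dropna()
    meta = table.drop_duplicates(unit).set_index(unit).loc[wide.index]
    rows = []
    for b in levels_b:
        sel = wide[meta[between] == b]
        r = t_test(sel[levels_w[1]], sel[levels_w[0]], mode="paired")
        rows.append((f"{between}={b}", f"{levels_w[1]} vs {levels_w[0]}",
                     r.t, r.df, r.p, r.cohens_d))
    for w in levels_w:
        a = wide.loc[meta[between] == levels_b[0], w]
        c = wide.loc[meta[between] == levels_b[1], w]
        r = t_test(a, c, mode="independent")
        rows.append((f"{within}={w}", f"{levels_b[0]} vs {levels_b[1]}",
                     r.t, r.df, r.p, r.cohens_d))
    return pd.DataFrame(rows, columns=["at", "contrast", "t", "df", "p", "cohens_d"])
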