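"""Land-cover change and its association with temporal dissimilarity.

Change per site and variable is expressed two ways: the raw difference
``delta = v_t2 - v_t1`` (same units as v) and a standardised change
``std = (v_t2 - v_t1) / (v_t2 + v_t1 + 1)`` that weights an absolute change
by the amount of that cover present (the +1 avoids a null denominator and
bounds the ratio in (-1, 1)).

Dissimilarity is regressed on change with a piecewise (breakpoint-at-zero)
linear model, because assemblages may respond differently to gains than to
losses of a cover.  Two regression lines are fitted, one per sign of the
change, discontinuous at zero; sites with exactly zero change — common,
since a cover absent at both dates has not changed — form their own level
at the breakpoint.  That yields five estimable coefficients and an overall
F with df (4, n-5), e.g. (4, 247) at 252 sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import LANDCOVER_VARIABLES, LandCoverTable

__all__ = ["LandCoverChange", "PiecewiseFit", "compute_change", "piecewise_fit", "fit_all"]


@dataclass(frozen=True)
class LandCoverChange:
    """Per-site change between two dates: columns ``delta_<v>`` and ``std_<v>``."""

    frame: pd.DataFrame

    @property
    def site_ids(self) -> tuple:
        return tuple(self.frame.index)

    def column(self, variable: str, standardized: bool = False) -> np.ndarray:
        prefix = "std" if standardized else "delta"
        return self.frame[f"{prefix}_{variable}"].to_numpy(float)


@dataclass(frozen=True)
class PiecewiseFit:
    """OLS piecewise fit summary.

    ``coefficients`` are (intercept, slope_neg, level_shift, slope_pos_delta):
    the positive branch has intercept ``intercept + level_shift`` and slope
    ``slope_neg + slope_pos_delta``.
    """

    coefficients: tuple[float, float, float, float]
    r2: float
    F: float
    df: tuple[int, int]
    p: float
    n: int
    degenerate: bool = False  # y constant, or x single-signed (simple-line fallback)


def compute_change(lc_t1: LandCoverTable, lc_t2: LandCoverTable) -> LandCoverChange:
    """Delta and standardised change per variable per site between two dates."""
    if lc_t1.site_ids != lc_t2.site_ids:
        raise ValueError("land-cover tables must cover the same sites in the same order")
    out = {}
    for v in LANDCOVER_VARIABLES:
        a = lc_t1.frame[v].to_numpy(float)
        b = lc_t2.frame[v].to_numpy(float)
        out[f"delta_{v}"] = b - a
        out[f"std_{v}"] = (b - a) / (b + a + 1)
    return LandCoverChange(frame=pd.DataFrame(out, index=list(lc_t1.site_ids)))


def piecewise_fit(y, x) -> PiecewiseFit:
    """Regress dissimilarity on land-cover change with a breakpoint at zero.

    Separate regression lines are fitted for negative and positive change;
    sites with exactly zero change (no change in that cover) form their own
    level at the breakpoint.  With zero-change sites present the model has
    five estimable coefficients, so the overall F against the intercept-only
    model carries df (4, n-5) — e.g. (4, 247) for 252 sites; without any
    exact zeros the zero level is empty and df are (3, n-4).  If x does not
    contain both signs the model degenerates to a simple regression line
    (df (1, n-2)) and is flagged; constant y returns r2=0, F=0, flagged.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D of equal length")
    n = y.size
    if n < 6:
        raise ValueError("piecewise fit needs at least 6 observations")
    if np.ptp(y) == 0:
        return PiecewiseFit((y[0], 0.0, 0.0, 0.0), 0.0, 0.0, (4, n - 5), 1.0, n, True)
    neg, pos = x < 0, x > 0
    zero = ~neg & ~pos
    both_signs = pos.any() and neg.any()
    if not both_signs:
        warnings.warn(
            "land-cover change has a single sign: falling back to a simple regression line",
            stacklevel=2,
        )
        X = np.column_stack([np.ones(n), x])
        res = sm.OLS(y, X).fit()
        coefs = (float(res.params[0]), float(res.params[1]), 0.0, 0.0)
    elif zero.any():
        # intercept = zero-change level; branch intercepts offset from it
        X = np.column_stack([np.ones(n), neg, pos, x * neg, x * pos])
        res = sm.OLS(y, X).fit()
        b = res.params
        coefs = (float(b[0] + b[1]), float(b[3]), float(b[2] - b[1]), float(b[4] - b[3]))
    else:
        X = np.column_stack([np.ones(n), pos.astype(float), x * neg, x * pos])
        res = sm.OLS(y, X).fit()
        b = res.params
        coefs = (float(b[0]), float(b[2]), float(b[1]), float(b[3] - b[2]))
    return PiecewiseFit(
        coefficients=coefs,
        r2=float(res.rsquared),
        F=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        p=float(res.f_pvalue),
        n=n,
        degenerate=not both_signs,
    )


def fit_all(
    dissim: dict[str, np.ndarray],
    change: LandCoverChange,
    standardized: bool = False,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Piecewise fits of each dissimilarity component on each land-cover variable.

    ``dissim`` maps component labels (e.g. "sim", "sne") to per-site values in
    the site order of ``change``.  Returns a tidy table with one row per
    (component, variable) and Bonferroni-adjusted p (default m = number of
    fits, i.e. 6 variables × 2 components = 12).
    """
    n_fits = len(dissim) * len(LANDCOVER_VARIABLES)
    m = bonferroni_m if bonferroni_m is not None else n_fits
    rows = []
    for comp, y in dissim.items():
        y = np.asarray(y, float)
        if y.shape[0] != len(change.site_ids):
            raise ValueError(f"component {comp!r} does not cover the change table's sites")
        for v in LANDCOVER_VARIABLES:
            fit = piecewise_fit(y, change.column(v, standardized=standardized))
            rows.append(
                {
                    "component": comp,
                    "variable": v,
                    "standardized": standardized,
                    "r2": fit.r2,
                    "F": fit.F,
                    "df1": fit.df[0],
                    "df2": fit.df[1],
                    "p": fit.p,
                    "p_bonferroni": min(1.0, m * fit.p),
                    "n": fit.n,
                    "degenerate": fit.degenerate,
                }
            )
    return pd.DataFrame(rows)
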