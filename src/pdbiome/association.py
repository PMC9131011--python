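"""Spearman association screening between clinical covariates and taxa.

Plain and partial (covariate-adjusted) Spearman correlations.  The
partial estimator is the rank-residual construction: rank-transform the
two variables and the numeric covariates, residualize both ranked
variables on the ranked covariates by least squares (with intercept),
and take the Pearson correlation of the residuals; p-values use the t
approximation with n - 2 - k degrees of freedom.  With no covariates
this reduces exactly to the ordinary Spearman coefficient.

Correlation strength is binned on |rho|: < 0.2 none, [0.2, 0.4) weak,
[0.4, 0.6) moderate, >= 0.6 strong, with values within 0.002 of a bin
boundary annotated as borderline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, relative_abundance

STRENGTH_BINS = ((0.2, "weak"), (0.4, "moderate"), (0.6, "strong"))
BORDERLINE_TOL = 0.002


def bin_strength(rho: float) -> str:
    """Strength label for a correlation coefficient in [-1, 1]."""
    if not -1.0 <= rho <= 1.0 or np.isnan(rho):
        raise ValueError("rho must lie in [-1, 1]")
    a = abs(rho)
    label = "none"
    for lo, name in STRENGTH_BINS:
        if a >= lo:
            label = name
    return label


def is_borderline(rho: float, tol: float = BORDERLINE_TOL) -> bool:
    """Whether |rho| sits within `tol` of a bin boundary."""
    a = abs(rho)
    return any(abs(a - lo) <= tol + 1e-12 for lo, _ in STRENGTH_BINS)


def _spearman_p(rho: float, n: int, k: int = 0) -> float:
    """Two-sided p from the t approximation with n - 2 - k df."""
    df = n - 2 - k
    if df <= 0 or abs(rho) >= 1.0:
        return 0.0 if abs(rho) >= 1.0 else np.nan
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df))


def _encode_numeric(col: pd.Series) -> pd.Series:
    """Binary string columns (e.g. sex) to 0/1; numeric passed through."""
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)
    levels = sorted(pd.unique(col.dropna()))
    if len(levels) > 2:
        raise ValueError(f"cannot encode non-binary column {col.name!r}")
    return col.map({lv: float(i) for i, lv in enumerate(levels)})


def partial_spearman(x, y, covariates: pd.DataFrame | None = None) -> tuple[float, float, int]:
    """Partial Spearman rho of x and y given covariates; returns
    (rho, p, n).  Complete cases only; needs >= k + 4 of them."""
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float)).set_axis(x.index)
    if covariates is None or covariates.shape[1] == 0:
        cov = pd.DataFrame(index=x.index)
    else:
        cov = pd.DataFrame(
            {c: _encode_numeric(covariates[c]).to_numpy() for c in covariates.columns},
            index=x.index,
        )
    frame = pd.concat([x.rename("__x"), y.rename("__y"), cov], axis=1).dropna()
    n, k = len(frame), cov.shape[1]
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} complete cases, got {n}")
    if frame["__x"].nunique() < 2 or frame["__y"].nunique() < 2:
        raise ValueError("constant variable: rho undefined")
    ranked = frame.apply(lambda c: stats.rankdata(c), axis=0)
    design = np.column_stack([np.ones(n), ranked.iloc[:, 2:].to_numpy()])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular covariate matrix")
    beta, *_ = np.linalg.lstsq(design, ranked.iloc[:, :2].to_numpy(), rcond=None)
    resid = ranked.iloc[:, :2].to_numpy() - design @ beta
    rho = float(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1])
    return rho, _spearman_p(rho, n, k), n


def spearman_screen(
    table: FeatureTable,
    metadata: pd.DataFrame,
    covariates: list[str],
    adjust_for: list[str] | None = None,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """All (covariate, taxon) Spearman correlations, long format.

    Taxa enter as relative abundances at the table's rank.  Pairs with
    missing metadata are dropped pairwise.  With `adjust_for`, partial
    Spearman correlations controlling for those columns are computed
    instead.  Constant vectors yield a missing rho with a recorded
    reason.
    """
    rel = relative_abundance(table)
    adjust = list(adjust_for or [])
    k = len(adjust)
    rows = []
    for cov_name in covariates:
        cov = _encode_numeric(metadata.loc[table.sample_ids, cov_name])
        for taxon in table.feature_ids:
            ab = rel.loc[taxon]
            pair = pd.DataFrame({"x": cov.to_numpy(), "y": ab.to_numpy()},
                                index=table.sample_ids)
            if adjust:
                pair = pd.concat(
                    [pair, metadata.loc[table.sample_ids, adjust]], axis=1
                )
            pair = pair.dropna()
            n = len(pair)
            base = {"covariate": cov_name, "taxon": taxon, "n": n,
                    "partial": bool(adjust)}
            if n < max(min_pairs, k + 4):
                rows.append({**base, "rho": np.nan, "p": np.nan,
                             "bin": "none", "reason": "too few complete pairs"})
                continue
            if pair["x"].nunique() < 2 or pair["y"].nunique() < 2:
                rows.append({**base, "rho": np.nan, "p": np.nan,
                             "bin": "none", "reason": "constant vector"})
                continue
            if adjust:
                rho, p, n = partial_spearman(
                    pair["x"], pair["y"], pair[adjust]
                )
            else:
                rho, p = stats.spearmanr(pair["x"], pair["y"])
                rho, p = float(rho), float(p)
            rows.append({**base, "rho": rho, "p": p,
                         "bin": bin_strength(rho), "reason": ""})
    return pd.DataFrame(rows)
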