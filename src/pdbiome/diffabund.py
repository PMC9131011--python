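"""Monte-Carlo Dirichlet + CLR differential abundance (ALDEx2-style).

For each sample the posterior of its composition is sampled as
Dirichlet(counts + 0.5); each Monte-Carlo instance is CLR-transformed
(log2 ratios to the geometric mean over *all* features) and a Welch
t-test comparing the two groups is run per feature, with
Benjamini-Hochberg adjustment across features within each instance.
Reported p-values are the expectation (arithmetic mean) over instances.

The effect size is the median between-group CLR difference divided by
the median within-group dispersion, and the fold change is
``2 ** (median CLR difference)``.  A volcano-style significance flag
combines ``-log10(p) > 3`` with ``|fold change| > 1.2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable


@dataclass
class DiffAbundanceResult:
    """Per-feature expected statistics over Monte-Carlo instances."""

    table: pd.DataFrame  # columns: p, p_bh, effect, log2fc, fold_change, significant
    n_mc: int
    groups: tuple[str, str]

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]


def dirichlet_instances(
    table: FeatureTable, n_mc: int = 128, prior: float = 0.5, seed: int | None = None
) -> np.ndarray:
    """Monte-Carlo proportion instances, shape (n_mc, features, samples).

    Each sample's column in each instance is one draw from
    Dirichlet(counts + prior) and sums to 1.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    if table.n_features < 1 or table.n_samples < 1:
        raise ValueError("empty table")
    rng = np.random.default_rng(seed)
    alpha = table.counts().T.astype(float) + prior  # samples x features
    # gamma-normalisation form of the Dirichlet, vectorised over instances
    g = rng.standard_gamma(alpha, size=(n_mc,) + alpha.shape)
    g /= g.sum(axis=2, keepdims=True)
    return np.transpose(g, (0, 2, 1))  # n_mc x features x samples


def clr(instance: np.ndarray) -> np.ndarray:
    """Centered log-ratio (base 2) of strictly positive proportions,
    features x samples; each sample's CLR values sum to zero."""
    p = np.asarray(instance, dtype=float)
    if (p <= 0).any():
        raise ValueError("CLR requires strictly positive proportions")
    l = np.log2(p)
    return l - l.mean(axis=-2, keepdims=True)


def _welch_t(a: np.ndarray, b: np.ndarray, axis: int = -1):
    """Welch t statistic and two-sided p along `axis` (groups a vs b)."""
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va, vb = a.var(axis=axis, ddof=1), b.var(axis=axis, ddof=1)
    se2 = va / na + vb / nb
    se2 = np.maximum(se2, 1e-300)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1) + 1e-300)
    df = np.maximum(df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def test_features(
    table: FeatureTable,
    metadata: pd.DataFrame,
    n_mc: int = 128,
    prior: float = 0.5,
    seed: int | None = None,
    group_col: str = "group",
) -> DiffAbundanceResult:
    """Expected Welch-t differential abundance between the two groups.

    Requires a binary group column with at least two samples per group.
    Deterministic given `seed`.
    """
    groups = metadata.loc[table.sample_ids, group_col]
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"group column must be binary, got levels {levels}")
    mask_a = (groups == levels[0]).to_numpy()
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    inst = dirichlet_instances(table, n_mc=n_mc, prior=prior, seed=seed)
    z = clr(inst)  # n_mc x features x samples
    za, zb = z[:, :, mask_a], z[:, :, ~mask_a]

    _, p = _welch_t(za, zb, axis=2)  # n_mc x features
    p_bh = np.stack([multipletests(row, method="fdr_bh")[1] for row in p])

    diff = za.mean(axis=2) - zb.mean(axis=2)  # per-instance mean CLR difference
    # ALDEx-style effect: median between-group difference over the median
    # pooled within-group dispersion (spread of CLR values around the group
    # means), per feature across instances
    disp = np.maximum(za.std(axis=2, ddof=1), zb.std(axis=2, ddof=1))
    effect = np.median(diff, axis=0) / np.maximum(np.median(disp, axis=0), 1e-12)
    log2fc = np.median(diff, axis=0)

    out = pd.DataFrame(
        {
            "p": p.mean(axis=0),
            "p_bh": p_bh.mean(axis=0),
            "effect": effect,
            "log2fc": log2fc,
            "fold_change": np.sign(log2fc) * 2.0 ** np.abs(log2fc),
        },
        index=table.feature_ids,
    )
    out["significant"] = flag_significant_frame(out)
    return DiffAbundanceResult(out, n_mc, (str(levels[0]), str(levels[1])))


def flag_significant_frame(
    table: pd.DataFrame,
    p_threshold_neglog: float = 3.0,
    fc_threshold: float = 1.2,
    use_adjusted: bool = False,
    log_base: float = 10.0,
) -> pd.Series:
    """Volcano flags: -log(p) > threshold AND |fold change| > threshold.

    `fold_change` is signed: magnitude 2^|median CLR difference|, sign of
    the group difference.
    """
    p = table["p_bh"] if use_adjusted else table["p"]
    neglog = -np.log(np.maximum(p, 1e-300)) / np.log(log_base)
    return (neglog > p_threshold_neglog) & (table["fold_change"].abs() > fc_threshold)


def flag_significant(
    result: DiffAbundanceResult,
    p_threshold_neglog: float = 3.0,
    fc_threshold: float = 1.2,
    use_adjusted: bool = False,
    log_base: float = 10.0,
) -> pd.Series:
    return flag_significant_frame(
        result.table, p_threshold_neglog, fc_threshold, use_adjusted, log_base
    )
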