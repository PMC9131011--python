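"""Alpha diversity, beta-diversity distances, ordination and PERMANOVA.

Distances (Bray-Curtis, unweighted/weighted UniFrac) are computed through
scikit-bio and returned as ``skbio.DistanceMatrix`` objects keyed by
sample ID.  PCoA is classical metric scaling of the Gower-centered
squared-distance matrix; PERMANOVA is implemented here directly because
the marginal-terms mode (each term tested against the model containing
all others, vegan's ``adonis2(by = "margin")``) and exact enumeration of
small two-group designs are both needed.

Conventions: Shannon entropy in nats, Simpson as the Gini-Simpson index
1 - sum(p_i^2), Bray-Curtis on raw counts, weighted UniFrac normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .tables import FeatureTable

# ---------------------------------------------------------------------------
# alpha diversity


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a single sample's counts")
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    return c / total


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(counts, inverse: bool = False) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (or inverse Simpson 1/sum p_i^2)."""
    p = _proportions(counts)
    d = float((p**2).sum())
    return 1.0 / d if inverse else 1.0 - d


def richness(counts) -> int:
    """Number of taxa with nonzero count."""
    c = np.asarray(counts, dtype=float)
    if c.sum() == 0:
        raise ValueError("all-zero sample")
    return int((c > 0).sum())


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon, Simpson and richness."""
    rows = {
        s: {
            "shannon": shannon(table.data[s]),
            "simpson": simpson(table.data[s]),
            "richness": richness(table.data[s]),
        }
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on raw counts:
    BC(u, v) = 1 - 2 sum min(u_i, v_i) / (sum u + sum v)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts().T.astype(float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample")
    return beta_diversity("braycurtis", counts, ids=table.sample_ids)


def unifrac(table: FeatureTable, tree: TreeNode, weighted: bool = False,
            normalized: bool = True) -> DistanceMatrix:
    """Unweighted or (normalized) weighted UniFrac between all samples.

    Table features must all be leaves of `tree`; the tree must be rooted
    with branch lengths.
    """
    counts = table.counts().T
    leaves = {t.name for t in tree.tips()}
    missing = [f for f in table.feature_ids if f not in leaves]
    if missing:
        raise ValueError(f"features absent from tree: {missing[:5]}")
    if weighted:
        return beta_diversity(
            "weighted_unifrac", counts, ids=table.sample_ids,
            taxa=table.feature_ids, tree=tree, normalized=normalized,
        )
    return beta_diversity(
        "unweighted_unifrac", counts, ids=table.sample_ids,
        taxa=table.feature_ids, tree=tree,
    )


# ---------------------------------------------------------------------------
# principal coordinates


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # over positive eigenvalues only


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported as-is but
    excluded from both the axes and the proportion-explained denominator.
    """
    n = dist.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        raise ValueError("n_axes cannot exceed n_samples - 1")
    g = _gower_center(np.asarray(dist.data, dtype=float) ** 2)
    eigvals, eigvecs = linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    k = min(n_axes, int(pos.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    prop = np.where(pos[:k], eigvals[:k], 0.0) / eigvals[pos].sum() if pos.any() else np.zeros(k)
    coords = pd.DataFrame(
        coords, index=list(dist.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, eigvals, prop)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    terms: list[str]
    pseudo_f: dict[str, float]
    r_squared: dict[str, float]
    p_value: dict[str, float]
    n_permutations: int


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, dict[str, slice]]:
    """Intercept + per-term columns; categoricals dummy-coded (drop first)."""
    cols = [np.ones((len(design), 1))]
    spans: dict[str, slice] = {}
    start = 1
    for term in design.columns:
        col = design[term]
        if col.isna().any():
            raise ValueError(f"design column {term!r} has missing values")
        if pd.api.types.is_numeric_dtype(col):
            block = col.to_numpy(float)[:, None]
        else:
            levels = pd.unique(col)
            if len(levels) < 2:
                raise ValueError(f"factor {term!r} has fewer than 2 levels")
            block = pd.get_dummies(col, drop_first=True).to_numpy(float)
        cols.append(block)
        spans[term] = slice(start, start + block.shape[1])
        start += block.shape[1]
    return np.hstack(cols), spans


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _rank(x: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(x))


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    n_permutations: int = 9999,
    marginal: bool = False,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F per term from hat-matrix projections of the Gower-centered
    inner-product matrix.  ``marginal`` tests each term against the model
    retaining all other terms (Type-III style); otherwise terms are added
    sequentially in column order.  P-values come from freely permuting
    sample labels: ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.

    With ``exact`` and a single two-level factor, every distinct
    assignment of labels to samples is enumerated instead of sampled and
    the p-value is the exact fraction of assignments with ``F >= F_obs``.
    """
    design = design.loc[list(dist.ids)]
    n = len(design)
    g = _gower_center(np.asarray(dist.data, dtype=float) ** 2)
    x_full, spans = _design_matrix(design)
    terms = list(spans)
    rank_full = _rank(x_full)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    h_full = _hat(x_full)
    ss_total = np.trace(g)
    resid_proj = np.eye(n) - h_full

    # per-term projection contrast: marginal drops the term from the full
    # model; sequential compares nested models in order
    contrasts: dict[str, tuple[np.ndarray, int]] = {}
    if marginal:
        for term in terms:
            keep = [0] + [
                j for t, sp in spans.items() if t != term for j in range(sp.start, sp.stop)
            ]
            x_red = x_full[:, sorted(keep)]
            df_term = rank_full - _rank(x_red)
            if df_term == 0:
                raise ValueError(f"term {term!r} is confounded with the other terms")
            contrasts[term] = (h_full - _hat(x_red), df_term)
    else:
        prev_cols = [0]
        prev_rank = 1
        h_prev = _hat(x_full[:, prev_cols])
        for term in terms:
            prev_cols = prev_cols + list(range(spans[term].start, spans[term].stop))
            x_cur = x_full[:, prev_cols]
            cur_rank = _rank(x_cur)
            df_term = cur_rank - prev_rank
            if df_term == 0:
                raise ValueError(f"term {term!r} is confounded with earlier terms")
            h_cur = _hat(x_cur)
            contrasts[term] = (h_cur - h_prev, df_term)
            h_prev, prev_rank = h_cur, cur_rank

    def f_stats(gm: np.ndarray) -> dict[str, float]:
        ss_res = float(np.sum(resid_proj * gm.T))
        out = {}
        for term, (proj, df_term) in contrasts.items():
            ss_term = float(np.sum(proj * gm.T))
            out[term] = (ss_term / df_term) / (ss_res / df_resid)
        return out

    f_obs = f_stats(g)
    ss_res_obs = float(np.sum(resid_proj * g.T))
    r2 = {
        term: float(np.sum(proj * g.T)) / ss_total
        for term, (proj, _) in contrasts.items()
    }

    if exact:
        if len(terms) != 1 or design[terms[0]].nunique() != 2:
            raise ValueError("exact enumeration requires a single two-level factor")
        labels = design[terms[0]].to_numpy()
        lvl = pd.unique(labels)
        k = int((labels == lvl[0]).sum())
        ge = total = 0
        for idx in combinations(range(n), k):
            perm_labels = np.full(n, 1)
            perm_labels[list(idx)] = 0
            x_perm, _ = _design_matrix(pd.DataFrame({terms[0]: perm_labels}))
            h = _hat(x_perm)
            ss_term = float(np.sum((h - np.ones((n, n)) / n) * g.T))
            ss_res = ss_total - ss_term
            df_term = contrasts[terms[0]][1]
            f = (ss_term / df_term) / (ss_res / df_resid)
            total += 1
            if f >= f_obs[terms[0]] - 1e-12:
                ge += 1
        p = {terms[0]: ge / total}
        return PermanovaResult(terms, f_obs, r2, p, total)

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        f_perm = f_stats(gp)
        for t in terms:
            if f_perm[t] >= f_obs[t] - 1e-12:
                exceed[t] += 1
    p = {t: (1 + exceed[t]) / (1 + n_permutations) for t in terms}
    return PermanovaResult(terms, f_obs, r2, p, n_permutations)
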