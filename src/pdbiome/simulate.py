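"""Synthetic PD/HC cohort generator.

Emulates the inputs of a 16S case-control gut-microbiome study: an ASV
count table with log-normal baseline abundances and Dirichlet-multinomial
per-sample noise, a nested random taxonomy, a random rooted phylogeny, and
sample metadata (group, age, sex, BMI, clinical scores, macronutrient
intakes).  Group effects are planted as log-scale shifts on a chosen set
of taxa; optionally the informative taxa differ between samples above and
below a macronutrient threshold, which is the structure that makes a
nutrient-partitioned two-stage classifier outperform a single model.

Default cohort shape follows the study design the package targets:
103 PD patients and 81 household controls, a few hundred ASVs, and
macronutrient distributions parameterised by the cohort's published
means and standard deviations.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``; draws are consumed in a fixed documented order
(taxonomy, tree, baselines, planted taxa, metadata, counts), so identical
configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .tables import FeatureTable, TaxonomyMap, RANKS
from .tables import write_counts, write_taxonomy, write_metadata

# cohort summary statistics (mean, sd) per group used to parameterise the
# metadata model; PD first, HC second
_META_NORMAL = {
    "age": ((67.1, 12.2), (62.4, 15.6)),
    "bmi": ((25.7, 5.2), (26.2, 4.6)),
    "ccs": ((7.2, 4.7), (3.1, 2.9)),
    "rome_iv": ((4.4, 3.5), (1.1, 1.4)),
    "bss": ((2.8, 1.5), (3.9, 1.3)),
    "ldq": ((8.3, 7.7), (4.6, 6.1)),
    "ipaq": ((1823.6, 1693.6), (2942.4, 2620.9)),
    "moca": ((24.4, 4.8), (27.6, 2.5)),
    "bdi": ((11.9, 8.8), (5.2, 5.5)),
    "sf36_pcs": ((51.6, 22.7), (79.9, 17.7)),
    "sf36_mcs": ((60.9, 22.2), (80.8, 17.4)),
}
# macronutrients are right-skewed; modelled log-normally with the published
# group means/SDs as the target arithmetic moments
_META_LOGNORMAL = {
    "protein_g": ((118.4, 79.3), (116.7, 74.5)),
    "fat_g": ((101.7, 49.7), (95.7, 43.6)),
    "carbohydrate_g": ((278.8, 161.8), (232.2, 124.8)),
    "sugar_g": ((153.3, 86.3), (118.7, 60.6)),
    "fiber_g": ((41.1, 31.2), (38.1, 22.7)),
}
# kJ per gram used for %-energy variables (Atwater-style factors)
KJ_PER_G = {"protein": 16.7, "carbohydrate": 16.7, "fat": 37.7}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Attributes
    ----------
    n_group_a, n_group_b : int
        Samples labelled PD (a) and HC (b).
    n_asv : int
        Number of ASVs.
    sequencing_depth_mean : int
        Mean library size; per-sample depths are log-normal around it.
    depth_dispersion : float
        Coefficient of variation of the per-sample depth.
    n_differential : int
        Number of planted group-differential taxa (per stratum when
        ``stratum_effect`` is set).
    effect_log2 : float
        Planted log2 fold change applied to PD samples on planted taxa.
    nutrient_threshold : float
        Boundary on ``stratum_variable`` separating the two strata.
    stratum_effect : bool
        If true, the planted taxa differ between the low and high strata:
        one set is overrepresented in PD below the threshold and
        underrepresented above it, the other set the reverse, and group
        prevalence shifts across the boundary (``stratum_label_coupling``).
    stratum_variable : str
        Metadata column carrying the stratum boundary.
    stratum_label_coupling : float
        P(sample falls in the high stratum | PD) when ``stratum_effect``
        is set; HC gets the complementary probability.  0.5 decouples
        group and stratum; values near 1 make the boundary sharply
        recoverable from the labels.
    dm_concentration : float
        Dirichlet concentration scale; smaller = more overdispersion.
    base_log_sigma : float
        SD of the log-normal baseline relative abundances.
    sample_log_sigma : float
        SD of the per-sample log-normal jitter around the baseline
        (biological between-sample variation).
    sex_rate_a, sex_rate_b : float
        P(male) per group; defaults balanced.
    seed : int
        Master seed for the cohort's single random stream.
    """

    n_group_a: int = 103
    n_group_b: int = 81
    n_asv: int = 300
    sequencing_depth_mean: int = 50_000
    depth_dispersion: float = 0.4
    n_differential: int = 10
    effect_log2: float = 1.0
    nutrient_threshold: float = 240.0
    stratum_effect: bool = False
    stratum_variable: str = "carbohydrate_g"
    stratum_label_coupling: float = 0.7
    dm_concentration: float = 1000.0
    base_log_sigma: float = 1.5
    sample_log_sigma: float = 0.8
    sex_rate_a: float = 0.5
    sex_rate_b: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 0 or self.n_group_b < 0 or self.n_group_a + self.n_group_b < 1:
            raise ValueError("need at least one sample")
        if self.n_asv < 1:
            raise ValueError("n_asv must be positive")
        if self.sequencing_depth_mean <= 0:
            raise ValueError("sequencing_depth_mean must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        need = 2 * self.n_differential if self.stratum_effect else self.n_differential
        if need > self.n_asv:
            raise ValueError("n_differential too large for n_asv")
        if self.n_differential < 0:
            raise ValueError("n_differential must be non-negative")
        if not 0.0 <= self.stratum_label_coupling <= 1.0:
            raise ValueError("stratum_label_coupling must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted ground truth."""

    counts: FeatureTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": out / "counts.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "metadata": out / "metadata.tsv",
            "tree": out / "tree.nwk",
        }
        write_counts(self.counts, paths["counts"])
        write_taxonomy(self.taxonomy, paths["taxonomy"])
        write_metadata(self.metadata, paths["metadata"])
        self.tree.write(str(paths["tree"]))
        return paths


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    var = np.log1p((sd / mean) ** 2)
    return np.log(mean) - var / 2.0, np.sqrt(var)


def generate_tree(asv_ids, seed: int) -> TreeNode:
    """Random binary rooted tree with exponential branch lengths over the
    given leaves (>= 2 required)."""
    asv_ids = list(asv_ids)
    if len(asv_ids) < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in asv_ids:
        leaf = TreeNode(name=name)
        leaf.length = float(rng.exponential(0.1)) + 1e-6
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(0.1)) + 1e-6
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def _generate_taxonomy(asv_ids, rng: np.random.Generator) -> TaxonomyMap:
    """Nested random taxonomy: each rank partitions the rank below, so
    genera < families < orders < phyla in count (scaled from a cohort of
    627 ASVs carrying 9 phyla / 31 orders / 48 families / 138 genera)."""
    n = len(asv_ids)
    scale = n / 627.0
    n_phy = max(2, round(9 * scale))
    n_cls = max(3, round(18 * scale))
    n_ord = max(4, round(31 * scale))
    n_fam = max(5, round(48 * scale))
    n_gen = max(6, min(n, round(138 * scale)))
    # parent assignment from the top down guarantees nesting
    cls_phy = rng.integers(0, n_phy, n_cls)
    ord_cls = rng.integers(0, n_cls, n_ord)
    fam_ord = rng.integers(0, n_ord, n_fam)
    gen_fam = rng.integers(0, n_fam, n_gen)
    asv_gen = rng.integers(0, n_gen, n)
    rows = []
    for k, asv in enumerate(asv_ids):
        g = asv_gen[k]
        f = gen_fam[g]
        o = fam_ord[f]
        c = ord_cls[o]
        p = cls_phy[c]
        rows.append(
            {
                "phylum": f"Phylum{p + 1:02d}",
                "class": f"Class{c + 1:02d}",
                "order": f"Order{o + 1:02d}",
                "family": f"Family{f + 1:02d}",
                "genus": f"Genus{g + 1:03d}",
            }
        )
    df = pd.DataFrame(rows, index=list(asv_ids))[list(RANKS)]
    # leave a small unassigned tail at the genus level, as real Silva
    # assignments do
    n_un = max(0, int(0.03 * n))
    if n_un:
        un = rng.choice(n, size=n_un, replace=False)
        df.iloc[un, df.columns.get_loc("genus")] = ""
    return TaxonomyMap(df)


def _generate_metadata(cfg: SimulationConfig, sample_ids, groups, rng) -> pd.DataFrame:
    n = len(sample_ids)
    is_pd = np.asarray(groups) == "PD"
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["group"] = groups
    sex_rate = np.where(is_pd, cfg.sex_rate_a, cfg.sex_rate_b)
    meta["sex"] = np.where(rng.random(n) < sex_rate, "M", "F")
    for col, ((m1, s1), (m2, s2)) in _META_NORMAL.items():
        m = np.where(is_pd, m1, m2)
        s = np.where(is_pd, s1, s2)
        vals = rng.normal(m, s)
        vals = np.clip(vals, 0.0, None)
        if col == "moca":
            vals = np.clip(np.round(vals), 0, 30)
        meta[col] = np.round(vals, 1)
    for col, ((m1, s1), (m2, s2)) in _META_LOGNORMAL.items():
        mu1, sg1 = _lognormal_params(m1, s1)
        mu2, sg2 = _lognormal_params(m2, s2)
        mu = np.where(is_pd, mu1, mu2)
        sg = np.where(is_pd, sg1, sg2)
        meta[col] = np.round(rng.lognormal(mu, sg), 1)
    if cfg.stratum_effect and cfg.stratum_variable in _META_LOGNORMAL:
        # couple group and stratum: redraw the partition nutrient from the
        # same group-wise log-normal truncated to the assigned side of the
        # threshold, so the boundary is recoverable from the labels
        col = cfg.stratum_variable
        (m1, s1), (m2, s2) = _META_LOGNORMAL[col]
        mu1, sg1 = _lognormal_params(m1, s1)
        mu2, sg2 = _lognormal_params(m2, s2)
        mu = np.where(is_pd, mu1, mu2)
        sg = np.where(is_pd, sg1, sg2)
        p_high = np.where(is_pd, cfg.stratum_label_coupling, 1.0 - cfg.stratum_label_coupling)
        high = rng.random(n) < p_high
        f_thr = stats.norm.cdf((np.log(cfg.nutrient_threshold) - mu) / sg)
        f_thr = np.clip(f_thr, 1e-9, 1 - 1e-9)
        u = np.where(high, f_thr + rng.random(n) * (1 - f_thr), rng.random(n) * f_thr)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        meta[col] = np.round(np.exp(mu + sg * stats.norm.ppf(u)), 1)
    # disease-specific scores: missing for HC
    updrs = np.round(np.clip(rng.normal(32.9, 17.7, n), 0, None), 1)
    led = np.round(np.clip(rng.normal(834.8, 527.3, n), 0, None), 1)
    meta["updrs_iii"] = np.where(is_pd, updrs, np.nan)
    meta["led_mg"] = np.where(is_pd, led, np.nan)
    # energy from macronutrient content plus a small non-macronutrient
    # residual (alcohol, organic acids), then %-energy columns
    macro_kj = (
        meta["protein_g"] * KJ_PER_G["protein"]
        + meta["carbohydrate_g"] * KJ_PER_G["carbohydrate"]
        + meta["fat_g"] * KJ_PER_G["fat"]
    )
    meta["energy_kj"] = np.round(macro_kj * rng.normal(1.05, 0.03, n), 1)
    for nutrient in ("protein", "fat", "carbohydrate"):
        meta[f"pct_energy_{nutrient}"] = np.round(
            100.0 * meta[f"{nutrient}_g"] * KJ_PER_G[nutrient] / meta["energy_kj"], 2
        )
    return meta


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate counts, taxonomy, tree and metadata for one cohort.

    Counts are drawn per sample as Dirichlet-multinomial around a shared
    log-normal baseline composition.  PD samples receive a ``+effect_log2``
    log2 shift on the planted taxa; with ``stratum_effect`` two disjoint
    planted sets act below/above ``nutrient_threshold`` on
    ``stratum_variable``.  The returned ``truth`` records the planted IDs
    per stratum and the threshold.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_group_a + cfg.n_group_b
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(cfg.n_asv)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    groups = ["PD"] * cfg.n_group_a + ["HC"] * cfg.n_group_b

    # draw order: taxonomy, tree, baselines, planted taxa, metadata, counts
    taxonomy = _generate_taxonomy(asv_ids, rng)
    tree = generate_tree(asv_ids, seed=int(rng.integers(0, 2**31 - 1)))
    base_log = rng.normal(0.0, cfg.base_log_sigma, cfg.n_asv)

    # plant effects on taxa of at least median baseline abundance so the
    # signal is detectable at realistic depths (widening the pool by
    # abundance rank when more taxa are requested than the upper half holds)
    need = 2 * cfg.n_differential if cfg.stratum_effect else cfg.n_differential
    by_abundance = np.argsort(base_log)[::-1]
    pool = by_abundance[: max(need, cfg.n_asv - cfg.n_asv // 2)]
    chosen = rng.choice(pool, size=need, replace=False) if need else np.array([], int)
    if cfg.stratum_effect:
        low_set = chosen[: cfg.n_differential]
        high_set = chosen[cfg.n_differential :]
    else:
        low_set = high_set = chosen

    metadata = _generate_metadata(cfg, sample_ids, groups, rng)

    is_pd = np.asarray(groups) == "PD"
    strat_vals = metadata[cfg.stratum_variable].to_numpy(float)
    in_low = strat_vals <= cfg.nutrient_threshold

    shift = np.zeros((n, cfg.n_asv))
    ln2_eff = np.log(2.0) * cfg.effect_log2
    for s in range(n):
        if not is_pd[s]:
            continue
        if cfg.stratum_effect:
            # opposed directions per stratum: what is overrepresented in
            # PD below the threshold is underrepresented above it, so a
            # single pooled model sees conflicting signals
            sign = 1.0 if in_low[s] else -1.0
            shift[s, low_set] += sign * ln2_eff
            shift[s, high_set] -= sign * ln2_eff
        else:
            shift[s, low_set] += ln2_eff

    depths_mu, depths_sg = _lognormal_params(
        float(cfg.sequencing_depth_mean), cfg.depth_dispersion * cfg.sequencing_depth_mean
    )
    depths = np.maximum(rng.lognormal(depths_mu, depths_sg, n).astype(np.int64), 100)

    counts = np.zeros((cfg.n_asv, n), dtype=np.int64)
    for s in range(n):
        logw = base_log + shift[s] + rng.normal(0.0, cfg.sample_log_sigma, cfg.n_asv)
        w = np.exp(logw)
        alpha = cfg.dm_concentration * w / w.sum()
        comp = rng.dirichlet(alpha)
        counts[:, s] = rng.multinomial(depths[s], comp)

    table = FeatureTable(
        pd.DataFrame(counts, index=asv_ids, columns=sample_ids), rank="asv"
    )
    truth = {
        "differential_low": [asv_ids[i] for i in low_set],  # up in PD-low
        "differential_high": [asv_ids[i] for i in high_set],  # up in PD-high
        "stratum_variable": cfg.stratum_variable,
        "nutrient_threshold": cfg.nutrient_threshold,
        "effect_log2": cfg.effect_log2,
        "stratum_effect": cfg.stratum_effect,
    }
    return SyntheticCohort(table, taxonomy, tree, metadata, truth)
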