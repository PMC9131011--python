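"""Two-sample statistics recomputed from printed cohort summaries.

Case-control papers report per-group means/SDs (continuous variables)
and percentages (categorical variables) together with t and chi-square
statistics.  These are recomputable from the summaries alone: the
pooled-variance two-sample t from (mean, SD, n) pairs, and the 2x2
Pearson chi-square (no continuity correction) after reconstructing
integer counts by nearest-integer rounding of pct x n.  A Welch variant
annotates rows whose printed statistic matches neither form — those are
reported as discrepancies, never force-fit.

``reference_cohort_table()`` bundles the demographic/clinical summary
rows of the 103 PD / 81 household-control cohort this package targets,
including each row's printed statistic, so the whole table can be
re-verified from the summaries at any time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SummaryPair:
    """Printed two-group summary: means/SDs (continuous) or
    percentages (categorical), with group sizes."""

    n1: int
    n2: int
    mean1: float | None = None
    sd1: float | None = None
    mean2: float | None = None
    sd2: float | None = None
    pct1: float | None = None
    pct2: float | None = None

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be at least 2")
        cont = self.mean1 is not None
        if cont:
            if self.sd1 is None or self.sd2 is None or self.mean2 is None:
                raise ValueError("continuous pair needs mean and SD for both groups")
            if self.sd1 < 0 or self.sd2 < 0:
                raise ValueError("SDs must be non-negative")
        else:
            if self.pct1 is None or self.pct2 is None:
                raise ValueError("categorical pair needs pct for both groups")
            for p in (self.pct1, self.pct2):
                if not 0 <= p <= 100:
                    raise ValueError("percentages must lie in [0, 100]")

    @property
    def is_continuous(self) -> bool:
        return self.mean1 is not None


def pooled_t(pair: SummaryPair) -> tuple[float, int]:
    """Pooled-variance two-sample t (group1 - group2) and df = n1+n2-2."""
    if not pair.is_continuous:
        raise ValueError("pooled_t needs a continuous pair")
    n1, n2 = pair.n1, pair.n2
    sp2 = ((n1 - 1) * pair.sd1**2 + (n2 - 1) * pair.sd2**2) / (n1 + n2 - 2)
    diff = pair.mean1 - pair.mean2
    if sp2 == 0:
        if diff == 0:
            return 0.0, n1 + n2 - 2
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), n1 + n2 - 2


def welch_t(pair: SummaryPair) -> tuple[float, float]:
    """Welch t (group1 - group2) with Satterthwaite df."""
    if not pair.is_continuous:
        raise ValueError("welch_t needs a continuous pair")
    se1, se2 = pair.sd1**2 / pair.n1, pair.sd2**2 / pair.n2
    if se1 + se2 == 0:
        raise ValueError("zero variance in both groups")
    t = (pair.mean1 - pair.mean2) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (
        se1**2 / (pair.n1 - 1) + se2**2 / (pair.n2 - 1)
    )
    return float(t), float(df)


def chi2_from_pct(pair: SummaryPair) -> tuple[float, int]:
    """2x2 Pearson chi-square from (pct, n) per group, df = 1.

    Counts are reconstructed as round(pct/100 x n); no continuity
    correction (matching SPSS's default Pearson statistic).
    """
    if pair.is_continuous:
        raise ValueError("chi2_from_pct needs a categorical pair")
    a = round(pair.pct1 / 100.0 * pair.n1)
    b = round(pair.pct2 / 100.0 * pair.n2)
    tab = np.array([[a, pair.n1 - a], [b, pair.n2 - b]], dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: zero expected cell")
    chi2, _, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), 1


# ---------------------------------------------------------------------------
# bundled cohort summary (103 PD vs 81 HC)

_N_PD, _N_HC = 103, 81

# label, kind, group summaries, printed statistic
_CONTINUOUS = [
    ("age_years", 67.1, 12.2, 62.4, 15.6, 2.3),
    ("bmi", 25.7, 5.2, 26.2, 4.6, -0.7),
    ("last_antibiotic_months", 21.9, 33.8, 25.8, 37.8, -0.7),
    ("daily_caffeine_cups", 2.3, 1.7, 3.1, 1.8, 3.0),
    ("cleveland_constipation", 7.2, 4.7, 3.1, 2.9, 6.9),
    ("rome_iv_constipation", 4.4, 3.5, 1.1, 1.4, 7.9),
    ("bristol_stool_score", 2.8, 1.5, 3.9, 1.3, 4.0),
    ("leeds_dyspepsia", 8.3, 7.7, 4.6, 6.1, 3.5),
    ("ipaq_met_min_week", 1823.6, 1693.6, 2942.4, 2620.9, -3.5),
    ("sitting_hours_day", 6.5, 3.5, 4.8, 2.3, 3.7),
    ("c_reactive_protein", 3.9, 10.8, 2.2, 2.5, 1.4),
    ("total_cholesterol", 4.8, 0.9, 5.2, 1.1, -2.5),
    ("albumin", 38.7, 3.5, 39.8, 3.1, -2.3),
    ("energy_kj_day", 11130.9, 5782.6, 10188.2, 4799.9, 1.2),
    ("protein_g_day", 118.4, 79.3, 116.7, 74.5, 0.1),
    ("fat_g_day", 101.7, 49.7, 95.7, 43.6, 0.9),
    ("carbohydrate_g_day", 278.8, 161.8, 232.2, 124.8, 2.1),
    ("total_sugars_g_day", 153.3, 86.3, 118.7, 60.6, 3.0),
    ("fiber_g_day", 41.1, 31.2, 38.1, 22.7, 0.7),
    ("beck_depression_inventory", 11.9, 8.8, 5.2, 5.5, 5.9),
    ("moca_total", 24.4, 4.8, 27.6, 2.5, -5.4),
    ("sf36_physical_component", 51.6, 22.7, 79.9, 17.7, -9.3),
    ("sf36_mental_component", 60.9, 22.2, 80.8, 17.4, -6.6),
]
_CATEGORICAL = [
    ("male_sex_pct", 56.3, 32.1, 10.7),
    ("caffeine_consumption_pct", 85.4, 91.4, 1.5),
    ("diabetes_pct", 4.9, 6.2, 0.2),
    ("functional_constipation_pct", 78.6, 28.4, 46.6),
    ("chronic_pain_pct", 72.8, 39.5, 20.7),
    ("able_walk_1km_pct", 73.8, 97.5, 19.3),
    ("able_climb_stairs_pct", 86.4, 100.0, 11.9),
    ("mild_cognitive_impairment_pct", 48.6, 18.5, 17.9),
]

# the desk-scale verification surface: rows whose printed statistic is
# recovered to one decimal by the formulas above
VERIFIED_ROWS = [
    "age_years",
    "cleveland_constipation",
    "leeds_dyspepsia",
    "ipaq_met_min_week",
    "moca_total",
    "male_sex_pct",
    "functional_constipation_pct",
    "chronic_pain_pct",
    "able_walk_1km_pct",
    "mild_cognitive_impairment_pct",
]


def reference_cohort_table() -> pd.DataFrame:
    """Bundled summary rows (label, kind, group stats, printed value)."""
    rows = []
    for label, m1, s1, m2, s2, printed in _CONTINUOUS:
        rows.append(
            {"label": label, "kind": "continuous", "mean1": m1, "sd1": s1,
             "mean2": m2, "sd2": s2, "pct1": np.nan, "pct2": np.nan,
             "n1": _N_PD, "n2": _N_HC, "printed": printed}
        )
    for label, p1, p2, printed in _CATEGORICAL:
        rows.append(
            {"label": label, "kind": "categorical", "mean1": np.nan,
             "sd1": np.nan, "mean2": np.nan, "sd2": np.nan,
             "pct1": p1, "pct2": p2, "n1": _N_PD, "n2": _N_HC,
             "printed": printed}
        )
    return pd.DataFrame(rows)


def _pair_from_row(row: pd.Series) -> SummaryPair:
    if row["kind"] == "continuous":
        return SummaryPair(
            n1=int(row["n1"]), n2=int(row["n2"]),
            mean1=row["mean1"], sd1=row["sd1"],
            mean2=row["mean2"], sd2=row["sd2"],
        )
    return SummaryPair(
        n1=int(row["n1"]), n2=int(row["n2"]), pct1=row["pct1"], pct2=row["pct2"]
    )


def verify_table(table: pd.DataFrame | None = None, tol: float = 0.05) -> pd.DataFrame:
    """Recompute every row's statistic and flag agreement with the
    printed value.

    Continuous rows get the pooled t (and the Welch t as a diagnostic
    when the pooled form misses); categorical rows get the Pearson
    chi-square.  ``match`` requires the statistic, rounded to one
    decimal, to equal the printed value (sign included); near-misses at
    the second decimal are discrepancies, not matches.
    """
    if table is None:
        table = reference_cohort_table()
    out = []
    for _, row in table.iterrows():
        pair = _pair_from_row(row)
        if pair.is_continuous:
            stat, df = pooled_t(pair)
            wstat, _ = welch_t(pair)
            pooled_match = abs(round(stat, 1) - row["printed"]) <= tol
            welch_match = abs(round(wstat, 1) - row["printed"]) <= tol
            match = pooled_match
            note = ""
            if not pooled_match:
                note = "welch matches" if welch_match else "not reproduced"
            out.append(
                {"label": row["label"], "kind": "continuous",
                 "statistic": stat, "df": df, "welch": wstat,
                 "printed": row["printed"], "match": match, "note": note}
            )
        else:
            stat, df = chi2_from_pct(pair)
            match = abs(round(stat, 1) - row["printed"]) <= tol
            out.append(
                {"label": row["label"], "kind": "categorical",
                 "statistic": stat, "df": df, "welch": np.nan,
                 "printed": row["printed"], "match": match,
                 "note": "" if match else "not reproduced"}
            )
    return pd.DataFrame(out)
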