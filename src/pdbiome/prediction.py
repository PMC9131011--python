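"""PD classifiers: single-stage random forest with leave-one-out AUC, and
the two-stage model that first partitions the cohort on a macronutrient
decision stump (maximum information gain) and then fits one forest per
sub-cohort, pooling all held-out scores into a single ROC/AUC.

The stump threshold is searched exhaustively over midpoints between
consecutive sorted distinct values of the nutrient.  By default the stump
is refit inside every leave-one-out training fold so the held-out sample
never influences its own partition; a reporting mode
(``refit_split_in_fold=False``) instead fits the stump once on the full
cohort, which reproduces published full-cohort split nodes but leaks the
held-out label into the partition and is flagged in the result.

AUC is the Mann-Whitney rank statistic with ties counted one half;
sensitivity/specificity are reported at the Youden-optimal ROC point.
Per-fold forest seeds are derived from the master seed and the held-out
sample's ID (not its position), so scores do not depend on sample order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

POSITIVE = "PD"


# ---------------------------------------------------------------------------
# entropy / stump


def entropy(labels) -> float:
    """Shannon entropy of a label vector, in bits."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(labels, variable, threshold: float) -> float:
    """Gain in bits of splitting `labels` at variable <= threshold."""
    labels = np.asarray(labels)
    v = np.asarray(variable, dtype=float)
    if np.isnan(v).any():
        raise ValueError("variable contains missing values")
    left = v <= threshold
    n_l, n_r = left.sum(), (~left).sum()
    if n_l == 0 or n_r == 0:
        raise ValueError("threshold leaves one side empty")
    n = len(labels)
    child = (n_l / n) * entropy(labels[left]) + (n_r / n) * entropy(labels[~left])
    return entropy(labels) - child


@dataclass
class StumpSplit:
    """A single-node decision tree on one numeric variable."""

    variable: str
    threshold: float
    gain: float  # bits


def fit_stump(
    variable_values, labels, variable_name: str = "", min_leaf: int | None = None
) -> StumpSplit:
    """Exhaustive maximum-information-gain threshold search.

    Candidate thresholds are midpoints between consecutive sorted
    distinct values; ties in gain break toward the lower threshold.
    Thresholds stranding fewer than `min_leaf` samples on a side are
    inadmissible (default 25% of the samples): the point of the split is
    to define two sub-cohorts each large enough to train a classifier
    on, so a noise-driven tail split may not carve off a vanishing
    sub-cohort.
    """
    v = np.asarray(variable_values, dtype=float)
    labels = np.asarray(labels)
    if min_leaf is None:
        min_leaf = max(1, int(np.floor(0.25 * len(v))))
    distinct = np.unique(v)
    if len(distinct) < 2:
        raise ValueError("variable has fewer than 2 distinct values")
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = (lo + hi) / 2.0
        n_low = int((v <= thr).sum())
        if n_low < min_leaf or len(v) - n_low < min_leaf:
            continue
        g = information_gain(labels, v, thr)
        if best is None or g > best.gain + 1e-12:
            best = StumpSplit(variable_name, float(thr), float(g))
    if best is None:
        raise ValueError("no admissible threshold (variable too concentrated)")
    return best


# ---------------------------------------------------------------------------
# ROC / AUC


def auc_mann_whitney(scores, labels, positive: str = POSITIVE) -> float:
    """AUC as the Mann-Whitney statistic; tied scores count one half."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, labels, positive: str = POSITIVE) -> pd.DataFrame:
    """ROC points from a sweep over the unique scores (descending),
    with (0,0) and (1,1) endpoints."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    n_pos, n_neg = pos.sum(), (~pos).sum()
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        rows.append(
            {
                "threshold": float(thr),
                "fpr": float((pred & ~pos).sum() / n_neg),
                "tpr": float((pred & pos).sum() / n_pos),
            }
        )
    return pd.DataFrame(rows)


def youden_point(roc: pd.DataFrame) -> pd.Series:
    """ROC row maximizing Youden's J = tpr - fpr (sensitivity =
    tpr, specificity = 1 - fpr)."""
    j = roc["tpr"] - roc["fpr"]
    return roc.iloc[int(j.to_numpy().argmax())]


# ---------------------------------------------------------------------------
# LOOCV harnesses


def _fold_seed(master_seed: int, sample_id: str) -> int:
    return (int(master_seed) * 1_000_003 + zlib.crc32(sample_id.encode())) % (2**31 - 1)


def _make_model(model: str, seed: int, n_estimators: int):
    if model == "random-forest":
        return RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    if model == "svm":
        return SVC(kernel="rbf", random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _score_one(model, x_train, y_train, x_test, positive: str) -> float:
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    model.fit(x_train, y_train)
    x_test = x_test.reshape(1, -1)
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(x_test)[0]
        return float(proba[list(model.classes_).index(positive)])
    # margin classifiers: signed distance to the boundary, oriented so
    # larger means more PD-like
    margin = float(model.decision_function(x_test)[0])
    return margin if model.classes_[1] == positive else -margin


def loocv_single(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    model: str = "random-forest",
    n_estimators: int = 500,
) -> tuple[pd.Series, float]:
    """Leave-one-out scores and AUC of a single classifier.

    `features` is samples x predictors (relative abundances at the
    chosen rank); `labels` are PD/HC aligned to its index.
    """
    if len(features) < 10:
        raise ValueError("need at least 10 samples for LOOCV")
    features = features.sort_index()  # canonical order: results do not
    labels = labels.loc[features.index]  # depend on input row order
    if labels.nunique() != 2:
        raise ValueError("labels must be binary with both classes present")
    x = features.to_numpy(float)
    y = labels.to_numpy()
    scores = {}
    for i, sid in enumerate(features.index):
        mask = np.ones(len(x), bool)
        mask[i] = False
        clf = _make_model(model, _fold_seed(seed, sid), n_estimators)
        scores[sid] = _score_one(clf, x[mask], y[mask], x[i], POSITIVE)
    scores = pd.Series(scores, name="score")
    return scores, auc_mann_whitney(scores.to_numpy(), y)


@dataclass
class TwoStageModelResult:
    """Pooled leave-one-out result of the nutrient-partitioned model."""

    stump: StumpSplit | None  # None when the variable is constant
    scores: pd.Series  # one held-out score per sample
    auc: float
    roc: pd.DataFrame
    sensitivity: float
    specificity: float
    stratum_sizes: dict[str, int]
    stratum_auc: dict[str, float]  # per-stratum AUC of the pooled scores
    stratum_auc_weighted: float  # size-weighted mean, alternative pooling
    n_fallback: int  # folds scored by the whole-fold model (stratum < 5)
    refit_split_in_fold: bool
    single_stage_auc: float | None = None
    per_stratum_models: dict = field(default_factory=dict)


def loocv_two_stage(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    labels: pd.Series,
    variable: str,
    seed: int = 0,
    refit_split_in_fold: bool = True,
    model: str = "random-forest",
    n_estimators: int = 500,
    min_stratum: int = 5,
) -> TwoStageModelResult:
    """Two-stage LOOCV: nutrient stump partition, then per-stratum
    forests; all held-out scores pooled into one ROC/AUC.

    When a training stratum has fewer than `min_stratum` members the
    held-out sample is scored by a model on the whole training fold
    instead; such folds are counted in ``n_fallback``.
    """
    features = features.sort_index()
    labels = labels.loc[features.index]
    v = metadata.loc[features.index, variable].to_numpy(float)
    if np.isnan(v).any():
        raise ValueError(f"variable {variable!r} has missing values")
    x = features.to_numpy(float)
    y = labels.to_numpy()
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for LOOCV")

    degenerate = len(np.unique(v)) < 2
    full_stump = None if degenerate else fit_stump(v, y, variable)
    if not refit_split_in_fold:
        warnings.warn(
            "full-cohort stump: the held-out sample influences its own "
            "partition (information leakage); use refit_split_in_fold=True "
            "for honest cross-validation",
            stacklevel=2,
        )

    scores = {}
    n_fallback = 0
    assigned = {}
    for i, sid in enumerate(features.index):
        mask = np.ones(n, bool)
        mask[i] = False
        if degenerate:
            # constant nutrient: a single stratum, identical to loocv_single
            stump = None
        else:
            stump = fit_stump(v[mask], y[mask], variable) if refit_split_in_fold else full_stump
        if stump is None:
            assigned[sid] = "low"
            stratum = mask
        else:
            low = v[i] <= stump.threshold
            assigned[sid] = "low" if low else "high"
            stratum = mask & ((v <= stump.threshold) if low else (v > stump.threshold))
            if stratum.sum() < min_stratum or len(np.unique(y[stratum])) < 2:
                stratum = mask
                n_fallback += 1
        clf = _make_model(model, _fold_seed(seed, sid), n_estimators)
        scores[sid] = _score_one(clf, x[stratum], y[stratum], x[i], POSITIVE)
    scores = pd.Series(scores, name="score")

    auc = auc_mann_whitney(scores.to_numpy(), y)
    roc = roc_curve_points(scores.to_numpy(), y)
    opt = youden_point(roc)

    assigned = pd.Series(assigned)
    strat_auc = {}
    sizes = {}
    for name in ("low", "high"):
        in_s = assigned == name
        sizes[name] = int(in_s.sum())
        ys = y[in_s.to_numpy()]
        if len(np.unique(ys)) == 2:
            strat_auc[name] = auc_mann_whitney(scores[in_s].to_numpy(), ys)
    weighted = (
        sum(strat_auc[k] * sizes[k] for k in strat_auc) / sum(sizes[k] for k in strat_auc)
        if strat_auc
        else np.nan
    )

    return TwoStageModelResult(
        stump=full_stump,
        scores=scores,
        auc=auc,
        roc=roc,
        sensitivity=float(opt["tpr"]),
        specificity=float(1.0 - opt["fpr"]),
        stratum_sizes=sizes,
        stratum_auc=strat_auc,
        stratum_auc_weighted=float(weighted),
        n_fallback=n_fallback,
        refit_split_in_fold=refit_split_in_fold,
    )


def survey_macronutrients(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    labels: pd.Series,
    candidates: list[str],
    seed: int = 0,
    n_estimators: int = 500,
    refit_split_in_fold: bool = True,
) -> pd.DataFrame:
    """One two-stage model per candidate nutrient plus the single-stage
    baseline, sorted by AUC descending.  Deterministic given `seed`."""
    _, base_auc = loocv_single(
        features, labels, seed=seed, n_estimators=n_estimators
    )
    rows = [
        {"variable": "(single-stage)", "threshold": np.nan, "auc": base_auc}
    ]
    for cand in candidates:
        res = loocv_two_stage(
            features,
            metadata,
            labels,
            cand,
            seed=seed,
            n_estimators=n_estimators,
            refit_split_in_fold=refit_split_in_fold,
        )
        rows.append(
            {"variable": cand, "threshold": res.stump.threshold, "auc": res.auc}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("auc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
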