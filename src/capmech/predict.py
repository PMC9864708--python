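"""Random-forest prediction of vulnerability-index changes.

Baseline values of nine risk factors — five morphological (LA, PA, PB,
MinCapT, MeanCapT) and four mechanical (MaxCapS, MeanCapS, MaxCapSn,
MeanCapSn) — predict the binary change (+1 progression / -1 not) of a
chosen PVI between baseline and follow-up.  The estimator is a 50-tree
random forest under five-fold cross-validation repeated with fresh random
partitions; out-of-fold positive-class probabilities are averaged over
repeats, an ROC is swept over the averaged probabilities, and the
operating cutoff maximizes the Youden index (Sen + Spe - 1).  All 511
non-empty subsets of the nine predictors can be swept and ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "PredictionResult",
    "assemble_features",
    "cross_validated_probabilities",
    "metrics",
    "sweep_combinations",
    "improvement_report",
]

FEATURE_NAMES = (
    "LA", "PA", "PB", "MinCapT", "MeanCapT",
    "MaxCapS", "MeanCapS", "MaxCapSn", "MeanCapSn",
)


@dataclass
class FeatureTable:
    """Baseline features and the binary target for matched slices."""

    frame: pd.DataFrame  # indexed by slice_id, columns FEATURE_NAMES
    target: pd.Series  # +1 / -1 per slice
    index_name: str = "C"

    def __post_init__(self):
        missing = [c for c in FEATURE_NAMES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        self.frame = self.frame[list(FEATURE_NAMES)]
        if self.frame.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not set(np.unique(self.target)) <= {-1, 1}:
            raise ValueError("target must be +1/-1")
        if len(np.unique(self.target)) < 2:
            raise ValueError("need both outcome classes")
        if (self.target.value_counts() < 2).any():
            raise ValueError("need >= 2 slices per class")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_pos(self) -> int:
        return int((self.target == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.target == -1).sum())


def assemble_features(
    morph: pd.DataFrame, mech: pd.DataFrame, outcomes: pd.Series,
    index_name: str = "C",
) -> FeatureTable:
    """Join baseline morphology, baseline mechanics and pair outcomes.

    ``morph`` carries LA/PA/PB/MinCapT/MeanCapT and ``mech`` the four cap
    stress/strain columns, both indexed by slice_id; slices without cap
    statistics (no lipid core) are excluded with a log entry.  Mismatched
    ids raise, listing the orphans.
    """
    for df, name in ((morph, "morph"), (mech, "mech")):
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"{name}: duplicated slice ids {dup}")
    orphans = set(morph.index) ^ set(mech.index)
    if orphans:
        raise ValueError(f"slice ids not present in both tables: {sorted(orphans)}")
    joined = morph.join(mech, how="inner")
    has_cap = joined[list(FEATURE_NAMES)].notna().all(axis=1)
    dropped = joined.index[~has_cap]
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} slice(s) without cap statistics: "
            f"{list(dropped[:5])}...",
            stacklevel=2,
        )
    joined = joined[has_cap]
    target = outcomes.reindex(joined.index)
    if target.isna().any():
        raise ValueError("outcomes missing for some slices")
    return FeatureTable(joined, target.astype(int), index_name)


# ---------------------------------------------------------------------------

def _partition(rng: np.random.Generator, n: int, k: int = 5) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(idx, k)]


def _stratified_partition(rng, y: np.ndarray, k: int = 5) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        for i, m in enumerate(members):
            folds[i % k].append(int(m))
    return [np.sort(np.array(f)) for f in folds]


def cross_validated_probabilities(
    table: FeatureTable,
    subset: tuple[str, ...] | list[str],
    n_trees: int = 50,
    n_repeats: int = 100,
    seed: int = 0,
    n_folds: int = 5,
) -> np.ndarray:
    """Repeat-averaged out-of-fold positive-class probabilities.

    Each repeat draws a fresh unstratified 5-way partition (repartitioning
    up to 20 times if a training fold lacks a class, then falling back to a
    stratified split with a warning), fits a forest on four folds and
    scores the held-out fold; probabilities are the fraction of trees
    voting positive, averaged across repeats.  Deterministic in ``seed``.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("empty predictor subset")
    unknown = set(subset) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    X = table.frame[list(subset)].to_numpy()
    y = table.target.to_numpy()
    n = len(y)
    rng = np.random.default_rng(seed)
    probs = np.zeros(n)
    for _ in range(n_repeats):
        folds = None
        for _attempt in range(20):
            cand = _partition(rng, n, n_folds)
            ok = all(
                len(np.unique(np.delete(y, fold))) == 2 for fold in cand
            )
            if ok:
                folds = cand
                break
        if folds is None:
            warnings.warn("degenerate folds; falling back to stratified split",
                          stacklevel=2)
            folds = _stratified_partition(rng, y, n_folds)
        rep = np.zeros(n)
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(X[train], y[train])
            pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
            rep[fold] = clf.predict_proba(X[fold])[:, pos_col]
        probs += rep
    return probs / n_repeats


@dataclass(frozen=True)
class PredictionResult:
    """Operating-point metrics of one predictor subset."""

    predictor_subset: tuple[str, ...]
    acc: float
    sen: float
    spe: float
    auc: float
    cutoff: float
    n_pos: int
    n_neg: int

    @property
    def sen_plus_spe(self) -> float:
        return self.sen + self.spe


def metrics(probabilities: np.ndarray, targets: np.ndarray,
            subset: tuple[str, ...] = ()) -> PredictionResult:
    """ROC over all distinct cutoffs; operating point maximizes Youden.

    Acc = (TP+TN)/(TP+FP+TN+FN), Sen = TP/(TP+FN), Spe = TN/(TN+FP); AUC by
    trapezoid over the full ROC.  Cutoff ties resolve toward higher
    sensitivity.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(targets)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes in targets")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if np.ptp(p) == 0:
        # degenerate ROC: chance line
        return PredictionResult(subset, n_neg / (n_pos + n_neg), 0.0, 1.0,
                                0.5, float(p[0]), n_pos, n_neg)
    fpr, tpr, cuts = roc_curve(y, p, pos_label=1)
    auc = float(roc_auc_score(y, p))
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # roc_curve sorts thresholds descending; later entries have higher Sen
    pick = best[-1]
    cutoff = float(cuts[pick])
    sen = float(tpr[pick])
    spe = float(1.0 - fpr[pick])
    acc = (sen * n_pos + spe * n_neg) / (n_pos + n_neg)
    return PredictionResult(subset, acc, sen, spe, auc, cutoff, n_pos, n_neg)


def evaluate_subset(
    table: FeatureTable, subset, n_trees: int = 50, n_repeats: int = 100,
    seed: int = 0,
) -> PredictionResult:
    """Cross-validated probabilities + ROC metrics for one subset."""
    probs = cross_validated_probabilities(table, subset, n_trees, n_repeats, seed)
    return metrics(probs, table.target.to_numpy(), tuple(subset))


def sweep_combinations(
    table: FeatureTable,
    n_trees: int = 50,
    n_repeats: int = 100,
    seed: int = 0,
    features: tuple[str, ...] = FEATURE_NAMES,
    rank_by: str = "acc",
) -> list[PredictionResult]:
    """Evaluate every non-empty predictor subset (2^9 - 1 = 511 for nine).

    Results are ranked by accuracy by default (ties by AUC), AUC ranking
    optionally; each subset reuses the same base seed stream so the sweep
    is reproducible end to end.
    """
    subsets = [
        combo
        for r in range(1, len(features) + 1)
        for combo in combinations(features, r)
    ]
    results = []
    for i, subset in enumerate(subsets):
        results.append(
            evaluate_subset(table, subset, n_trees, n_repeats,
                            seed=seed + 7919 * i)
        )
    keyfun = {
        "acc": lambda r: (r.acc, r.auc),
        "auc": lambda r: (r.auc, r.acc),
    }[rank_by]
    return sorted(results, key=keyfun, reverse=True)


def best_single_and_combination(
    results: list[PredictionResult], rank_by: str = "acc"
) -> tuple[PredictionResult, PredictionResult]:
    """Best single predictor and best overall subset from a ranked sweep."""
    key = (lambda r: (r.acc, r.auc)) if rank_by == "acc" else (lambda r: (r.auc, r.acc))
    singles = [r for r in results if len(r.predictor_subset) == 1]
    return max(singles, key=key), max(results, key=key)


def improvement_report(
    per_index: dict[str, tuple[float, float, float]], ndigits: int = 1
) -> dict:
    """Accuracy improvements of best combination over best single predictor.

    ``per_index`` maps each PVI name to (best_combination_accuracy_percent,
    best_single_accuracy_percent, best_combination_auc).  Improvements are
    differences of the (rounded-as-reported) accuracies in percentage
    points; the report also carries the mean AUC and mean improvement.
    """
    improvements = {}
    aucs = {}
    for name, (acc_comb, acc_single, auc) in per_index.items():
        improvements[name] = round(
            round(acc_comb, ndigits) - round(acc_single, ndigits), ndigits
        )
        aucs[name] = auc
    mean_auc = round(float(np.mean(list(aucs.values()))), 3)
    mean_improvement = round(float(np.mean(list(improvements.values()))), ndigits)
    return {
        "improvement_points": improvements,
        "mean_improvement_points": mean_improvement,
        "auc": aucs,
        "mean_auc": mean_auc,
    }
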