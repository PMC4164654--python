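"""Incremental feature selection with jackknife-evaluated random forests.

For k = 1..N, a random-forest classifier is trained on the top-k features of
the mRMR table and evaluated by jackknife (leave-one-out) cross-validation:
each sample is predicted by a forest trained on the other n-1.  Performance
is summarized by sensitivity, specificity, accuracy and the Matthews
correlation coefficient (MCC); MCC is the main evaluator because the classes
are imbalanced.  The optimal feature set is the top-k prefix with maximal
jackknife MCC (smallest k on ties).

The forest defaults follow the classical Weka random-forest defaults: 10
unpruned trees with floor(log2(m)) + 1 candidate features per split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .feature_encoding import FeatureDescriptor


@dataclass(frozen=True)
class ConfusionCounts:
    """Aggregated prediction counts; positives are the sumoylation class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-forest configuration.

    ``split_rule`` controls the number of candidate features per split:
    ``"log2plus1"`` gives floor(log2(m)) + 1 (the classical Weka default);
    an integer value is used as-is.
    """

    n_trees: int = 10
    split_rule: Union[str, int] = "log2plus1"


def _max_features(spec: ClassifierSpec, m: int) -> int:
    if isinstance(spec.split_rule, int):
        return max(1, min(spec.split_rule, m))
    if spec.split_rule == "log2plus1":
        return max(1, min(int(math.floor(math.log2(m))) + 1, m))
    raise ValueError(f"unknown split rule {spec.split_rule!r}")


def compute_metrics(cc: ConfusionCounts) -> Metrics:
    """SN, SP, ACC and MCC from confusion counts.

    SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    SN (resp. SP) is undefined when the evaluation set holds no positives
    (resp. negatives) and raises; an MCC denominator of zero yields MCC = 0.
    """
    if cc.total == 0:
        raise ValueError("metrics are undefined for all-zero confusion counts")
    if cc.TP + cc.FN == 0:
        raise ValueError("sensitivity undefined: no positive samples")
    if cc.TN + cc.FP == 0:
        raise ValueError("specificity undefined: no negative samples")
    sn = cc.TP / (cc.TP + cc.FN)
    sp = cc.TN / (cc.TN + cc.FP)
    acc = (cc.TP + cc.TN) / cc.total
    denom = (
        (cc.TP + cc.FP) * (cc.TP + cc.FN) * (cc.TN + cc.FP) * (cc.TN + cc.FN)
    )
    mcc = 0.0 if denom == 0 else (cc.TP * cc.TN - cc.FP * cc.FN) / math.sqrt(denom)
    return Metrics(sensitivity=sn, specificity=sp, accuracy=acc, mcc=mcc)


def fold_seed(seed: int, fold: int) -> int:
    """Deterministic per-fold seed derived from the run seed."""
    ss = np.random.SeedSequence([int(seed), int(fold)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the ensemble-of-trees predictor (majority vote over the trees)."""
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=_max_features(spec, X.shape[1]),
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def _counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((y_pred == 1) & (y_true == 1))),
        TN=int(np.sum((y_pred == 0) & (y_true == 0))),
        FP=int(np.sum((y_pred == 1) & (y_true == 0))),
        FN=int(np.sum((y_pred == 0) & (y_true == 1))),
    )


def jackknife_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
    folds: Optional[int] = None,
) -> ConfusionCounts:
    """Leave-one-out evaluation: predict each sample from the other n-1.

    Forest randomness is controlled per fold by a seed derived
    deterministically from ``(seed, fold index)``.  ``folds`` switches to
    stratified k-fold cross-validation, a cheaper stand-in for the strict
    jackknife on large problems.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n = X.shape[0]
    if np.unique(y).size < 2:
        raise ValueError("evaluation data must contain both classes")
    pred = np.empty(n, dtype=int)
    if folds is None:
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            if np.unique(y[mask]).size < 2:
                raise ValueError("a training fold contains a single class")
            clf = train_classifier(X[mask], y[mask], spec, fold_seed(seed, i))
            pred[i] = clf.predict(X[i : i + 1])[0]
            mask[i] = True
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for f, (train, test) in enumerate(splitter.split(X, y)):
            clf = train_classifier(X[train], y[train], spec, fold_seed(seed, f))
            pred[test] = clf.predict(X[test])
    return _counts_from_predictions(y, pred)


@dataclass
class IFSResult:
    """Per-k jackknife results plus the MCC-optimal prefix.

    ``records`` has one row per evaluated k with the confusion counts and
    metrics (NaN metrics for ks whose classifier could not be built);
    ``optimal_features`` is the top-``optimal_k`` block of the mRMR table.
    """

    records: pd.DataFrame
    optimal_k: int
    optimal_features: pd.DataFrame

    @property
    def optimal_mcc(self) -> float:
        row = self.records.loc[self.records["k"] == self.optimal_k]
        return float(row["MCC"].iloc[0])

    def optimal_descriptor_keys(self) -> list[tuple[str, int, str]]:
        return [
            (str(r.block), int(r.site), str(r.subtype))
            for r in self.optimal_features.itertuples(index=False)
        ]


def ifs_curve(
    mrmr_table: pd.DataFrame,
    X: np.ndarray,
    y: np.ndarray,
    k_min: int = 1,
    k_max: Optional[int] = None,
    k_step: int = 1,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
    folds: Optional[int] = None,
) -> IFSResult:
    """Evaluate top-k prefixes of the mRMR table for k on a grid.

    One jackknife evaluation is run per k in ``range(k_min, k_max+1,
    k_step)``, restricted to the top-k ranked feature columns.  ks whose
    classifier cannot be built are recorded with NaN metrics rather than
    failing the run.  The optimal k maximizes MCC (smallest k on ties).
    """
    if len(mrmr_table) == 0:
        raise ValueError("empty mRMR table")
    order = mrmr_table.sort_values("rank")["index"].to_numpy(dtype=int)
    X = np.asarray(X)
    if k_max is None:
        k_max = len(order)
    if k_max > len(order):
        raise ValueError(f"k_max={k_max} exceeds the {len(order)} ranked features")

    rows = []
    best_k, best_mcc = None, -np.inf
    for k in range(k_min, k_max + 1, k_step):
        cols = order[:k]
        row: dict = {"k": k}
        try:
            cc = jackknife_evaluate(X[:, cols], y, spec, seed, folds)
            m = compute_metrics(cc)
            row.update(
                TP=cc.TP, TN=cc.TN, FP=cc.FP, FN=cc.FN,
                SN=m.sensitivity, SP=m.specificity, ACC=m.accuracy, MCC=m.mcc,
            )
            if m.mcc > best_mcc:
                best_k, best_mcc = k, m.mcc
        except ValueError:
            row.update(TP=np.nan, TN=np.nan, FP=np.nan, FN=np.nan,
                       SN=np.nan, SP=np.nan, ACC=np.nan, MCC=np.nan)
        rows.append(row)
    records = pd.DataFrame(rows)
    if best_k is None:
        raise ValueError("no k on the grid produced a classifier")
    optimal = mrmr_table.sort_values("rank").head(best_k).reset_index(drop=True)
    return IFSResult(records=records, optimal_k=best_k, optimal_features=optimal)


def foldsafe_ifs_curve(
    X: np.ndarray,
    y: np.ndarray,
    descriptors: Optional[Sequence[FeatureDescriptor]] = None,
    k_min: int = 1,
    k_max: Optional[int] = None,
    k_step: int = 1,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Leakage-free IFS: re-rank features inside every leave-one-out fold.

    The mRMR table is recomputed on each training set of n-1 samples, and the
    held-out sample is predicted from that fold's own top-k prefix.  This is
    quadratically more expensive than :func:`ifs_curve` and is intended for
    small diagnostic runs; it returns the per-k metrics table only.
    """
    from .mrmr import discretize_matrix, mrmr_rank

    X = np.asarray(X)
    y = np.asarray(y)
    n, p = X.shape
    if k_max is None:
        k_max = p
    ks = list(range(k_min, k_max + 1, k_step))
    fold_orders = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        table = mrmr_rank(discretize_matrix(X[mask], y[mask]))
        fold_orders.append(table.sort_values("rank")["index"].to_numpy(dtype=int))
        mask[i] = True
    rows = []
    for k in ks:
        pred = np.empty(n, dtype=int)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            cols = fold_orders[i][:k]
            mask[i] = False
            clf = train_classifier(X[np.ix_(mask, cols)], y[mask], spec, fold_seed(seed, i))
            pred[i] = clf.predict(X[i : i + 1, cols])[0]
            mask[i] = True
        m = compute_metrics(_counts_from_predictions(y, pred))
        rows.append({"k": k, "SN": m.sensitivity, "SP": m.specificity,
                     "ACC": m.accuracy, "MCC": m.mcc})
    return pd.DataFrame(rows)
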