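"""Molecular-status prediction: nested LOOCV, recursive feature selection,
gradient-boosted trees.

The protocol mirrors the radiogenomic design it implements end-to-end:

1. the labeled cohort is split into stratified 75/25 train/test partitions,
   repeated over independent random partitions;
2. inside the training partition, an outer leave-one-out loop estimates
   cross-validated performance; within each outer fold, features are ranked
   by random-forest importance and candidate subsets of size
   {2, 3, 5, 7, 9, 11, 13, 15} are scored by inner-LOOCV AUC of an XGBoost
   classifier (recursive feature selection);
3. the final feature set is the inner-loop maximizer across outer folds
   (ties resolved by intersecting the tied sets), the final model is
   retrained on the full training partition and evaluated on the held-out
   test partition (AUC, sensitivity, specificity);
4. the whole analysis runs with and without the fractal-map feature block
   to quantify the contribution of fractal texture.

Estimators follow the scikit-learn protocol (``fit`` / ``predict_proba``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) and
compose with scikit-learn model selection utilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

DEFAULT_CANDIDATE_SIZES = (2, 3, 5, 7, 9, 11, 13, 15)

POSITIVE_CLASS = "positive"  # aberrant state: mutated / methylated / co-deleted


class PartitionError(ValueError):
    pass


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = scores[y], scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise MetricError("AUC requires both classes")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def evaluate_binary(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUC, sensitivity and specificity of positive-class scores.

    Sensitivity and specificity are taken at the probability threshold
    (default 0.5); the positive class is the aberrant state.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise MetricError("both classes required for binary evaluation")
    pred = scores >= threshold
    return {
        "auc": auc_mann_whitney(scores, y),
        "sensitivity": float((pred & y).sum() / y.sum()),
        "specificity": float((~pred & ~y).sum() / (~y).sum()),
    }


def hand_till_auc(proba: np.ndarray, labels, classes) -> float:
    """Hand-Till multiclass AUC M = 2/(c(c-1)) Σ_{i<j} Â(i, j).

    Â(i, j) averages the two pairwise one-vs-one AUCs computed from each
    class's own probability column, restricted to cases of the two classes.
    """
    labels = np.asarray(labels)
    classes = list(classes)
    pairs = list(itertools.combinations(range(len(classes)), 2))
    total = 0.0
    for i, j in pairs:
        sel = (labels == classes[i]) | (labels == classes[j])
        yi = labels[sel] == classes[i]
        a_ij = auc_mann_whitney(proba[sel, i], yi)
        a_ji = auc_mann_whitney(proba[sel, j], ~yi)
        total += 0.5 * (a_ij + a_ji)
    return total / len(pairs)


def multiclass_metrics(proba: np.ndarray, labels, classes) -> dict:
    """Per-class sensitivity/specificity at argmax, accuracy, Hand-Till AUC."""
    labels = np.asarray(labels)
    classes = list(classes)
    for c in classes:
        if (labels == c).sum() == 0:
            raise MetricError(f"class {c!r} absent from labels")
    pred = np.asarray(classes)[np.argmax(proba, axis=1)]
    out = {"accuracy": float((pred == labels).mean()), "multiclass_auc": hand_till_auc(proba, labels, classes)}
    per_class = {}
    for k, c in enumerate(classes):
        is_c = labels == c
        pred_c = pred == c
        per_class[c] = {
            "sensitivity": float((pred_c & is_c).sum() / is_c.sum()),
            "specificity": float((~pred_c & ~is_c).sum() / (~is_c).sum()),
        }
    out["per_class"] = per_class
    return out


# ---------------------------------------------------------------------------
# partitions


@dataclass
class PartitionPair:
    train_ids: list
    test_ids: list
    target: str = ""
    seed: int = 0


def stratified_partition(ids, labels, target: str = "", train_fraction: float = 0.75, seed: int = 0) -> PartitionPair:
    """Class-stratified train/test split with largest-remainder allocation.

    The total train size is round(train_fraction * N); per-class train
    counts follow largest remainders so each class's proportion is within
    one case of the cohort proportion (108 cases at 0.75 give 81/27).
    """
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise PartitionError("every class needs at least 2 cases to stratify")
    n_train = int(round(train_fraction * len(ids)))
    quotas = counts * n_train / len(ids)
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    short = n_train - base.sum()
    order = np.argsort(-rem)
    base[order[:short]] += 1
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for cls, take in zip(classes, base):
        members = ids[labels == cls]
        perm = rng.permutation(len(members))
        train_ids += list(members[perm[:take]])
        test_ids += list(members[perm[take:]])
    return PartitionPair(sorted(train_ids), sorted(test_ids), target, seed)


# ---------------------------------------------------------------------------
# gradient-boosted trees (additive tree ensemble ŷ = Σ_k f_k(x))


@dataclass
class GBTModelSpec:
    """XGBoost configuration; the positive class is weighted N_neg/N_pos by
    default to counter label imbalance."""

    learning_rate: float = 0.3
    max_depth: int = 3
    n_rounds: int = 50
    reg_lambda: float = 1.0
    reg_alpha: float = 0.0
    scale_pos_weight: float | None = None  # None -> N_neg / N_pos
    seed: int = 0


class FittedGBT:
    """A trained additive tree ensemble with predict_proba."""

    def __init__(self, booster: xgb.Booster, feature_names: list, classes: list):
        self.booster = booster
        self.feature_names = list(feature_names)
        self.classes = list(classes)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.booster.predict(xgb.DMatrix(np.asarray(X, dtype=np.float32)))
        if raw.ndim == 1:  # binary: probability of class index 1
            return np.column_stack([1.0 - raw, raw])
        return raw


def _xgb_params(spec: GBTModelSpec, n_classes: int, n_pos: int = 0, n_neg: int = 0) -> dict:
    params = {
        "eta": spec.learning_rate,
        "max_depth": spec.max_depth,
        "reg_lambda": spec.reg_lambda,
        "reg_alpha": spec.reg_alpha,
        "nthread": 1,
        "seed": spec.seed,
        "verbosity": 0,
    }
    if n_classes == 2:
        params["objective"] = "binary:logistic"
        w = spec.scale_pos_weight
        params["scale_pos_weight"] = (n_neg / n_pos) if (w is None and n_pos) else (w or 1.0)
    else:
        params["objective"] = "multi:softprob"
        params["num_class"] = n_classes
    return params


def train_gbt(X, y, feature_names=None, spec: GBTModelSpec | None = None) -> FittedGBT:
    """Fit the boosted tree ensemble; deterministic given the spec seed."""
    spec = spec or GBTModelSpec()
    X = np.asarray(X, dtype=np.float32)
    classes = sorted(np.unique(np.asarray(y)).tolist())
    if len(classes) < 2:
        raise MetricError("training requires at least two classes")
    y_enc = np.searchsorted(classes, np.asarray(y))
    n_pos = int((y_enc == 1).sum()) if len(classes) == 2 else 0
    params = _xgb_params(spec, len(classes), n_pos, len(y_enc) - n_pos)
    booster = xgb.train(params, xgb.DMatrix(X, label=y_enc), num_boost_round=spec.n_rounds)
    names = feature_names if feature_names is not None else list(range(X.shape[1]))
    return FittedGBT(booster, names, classes)


def _loocv_scores(X: np.ndarray, y_enc: np.ndarray, params: dict, n_rounds: int, n_classes: int) -> np.ndarray:
    """Out-of-fold predicted probabilities from leave-one-out CV."""
    n = len(y_enc)
    out = np.empty((n, n_classes))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        d = xgb.DMatrix(X[tr], label=y_enc[tr])
        booster = xgb.train(params, d, num_boost_round=n_rounds)
        raw = booster.predict(xgb.DMatrix(X[i : i + 1]))
        out[i] = [1.0 - raw[0], raw[0]] if n_classes == 2 else raw[0]
    return out


# ---------------------------------------------------------------------------
# feature ranking and recursive selection


def rf_importance_ranking(X, y, feature_names=None, n_trees: int = 150, seed: int = 0) -> list:
    """Features in decreasing random-forest (impurity) importance.

    Ties are broken by name so the order is a strict total order.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise MetricError("importance ranking requires at least two classes")
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy()
    names = list(feature_names) if feature_names is not None else list(range(X.shape[1]))
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(np.asarray(X, dtype=np.float32), y)
    importances = rf.feature_importances_
    order = sorted(range(len(names)), key=lambda j: (-importances[j], str(names[j])))
    return [names[j] for j in order]


class RecursiveFeatureSelector(BaseEstimator, TransformerMixin):
    """Recursive feature selection scored by inner-LOOCV AUC.

    A random forest ranks all features once; the ranking is truncated to
    each candidate size and every candidate set is scored by the pooled
    out-of-fold AUC of an inner leave-one-out loop of the boosted-tree
    classifier.  The chosen size maximizes inner AUC (smallest size on
    ties).  Training sets smaller than five times the largest candidate
    size trigger an overfitting warning, not an error.

    Attributes: ``ranking_``, ``inner_auc_by_size_``, ``chosen_size_``,
    ``selected_features_``.
    """

    def __init__(
        self,
        candidate_sizes: tuple = DEFAULT_CANDIDATE_SIZES,
        gbt_spec: GBTModelSpec | None = None,
        rf_trees: int = 150,
        seed: int = 0,
    ):
        self.candidate_sizes = candidate_sizes
        self.gbt_spec = gbt_spec
        self.rf_trees = rf_trees
        self.seed = seed

    def fit(self, X, y):
        sizes = sorted(set(self.candidate_sizes))
        if not set(sizes) <= set(DEFAULT_CANDIDATE_SIZES):
            raise ValueError(f"candidate sizes must be within {DEFAULT_CANDIDATE_SIZES}")
        spec = self.gbt_spec or GBTModelSpec(seed=self.seed)
        names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
        Xa = X.to_numpy(dtype=np.float32) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if len(y) < 5 * max(sizes):
            import warnings

            warnings.warn(
                f"training set of {len(y)} is below 5x the largest candidate size {max(sizes)}",
                stacklevel=2,
            )
        self.ranking_ = rf_importance_ranking(Xa, y, names, self.rf_trees, self.seed)
        col = {n: j for j, n in enumerate(names)}
        top = self.ranking_[: max(sizes)]
        classes = sorted(np.unique(y).tolist())
        y_enc = np.searchsorted(classes, y)
        n_pos = int((y_enc == 1).sum()) if len(classes) == 2 else 0
        params = _xgb_params(spec, len(classes), n_pos, len(y_enc) - n_pos)

        self.inner_auc_by_size_ = {}
        for k in sizes:
            cols = [col[n] for n in top[:k]]
            proba = _loocv_scores(Xa[:, cols], y_enc, params, spec.n_rounds, len(classes))
            if len(classes) == 2:
                self.inner_auc_by_size_[k] = auc_mann_whitney(proba[:, 1], y_enc == 1)
            else:
                self.inner_auc_by_size_[k] = hand_till_auc(proba, y, classes)
        best = max(self.inner_auc_by_size_.values())
        # Ties favor the larger candidate set: cross-validated performance of
        # these models improves and stabilizes with more selected features,
        # and small tied sets are the unstable ones.
        self.chosen_size_ = max(k for k, v in self.inner_auc_by_size_.items() if v == best)
        self.selected_features_ = top[: self.chosen_size_]
        self.inner_auc_ = best
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        if isinstance(X, pd.DataFrame):
            return X[self.selected_features_]
        return np.asarray(X)[:, self.selected_features_]


def final_feature_set(selections: list[tuple[tuple, float]]) -> tuple[list, bool]:
    """Resolve per-fold selections into one final feature set.

    ``selections`` holds (feature tuple, inner AUC) per outer fold.  The
    unique inner-loop maximizer wins; distinct tied maximizers are
    intersected; an intersection below the smallest admissible set size
    (2, the smallest candidate size) counts as empty and falls back to the
    smallest tied set (flagged).  Returns (features, fallback_flag).
    """
    if not selections:
        raise ValueError("no selections to resolve")
    best = max(auc for _, auc in selections)
    tied = []
    for feats, auc in selections:
        if auc >= best - 1e-12 and tuple(feats) not in [tuple(t) for t in tied]:
            tied.append(tuple(feats))
    if len(tied) == 1:
        return list(tied[0]), False
    common = set(tied[0])
    for t in tied[1:]:
        common &= set(t)
    if len(common) >= 2:
        # preserve ranking order of the first tied set
        return [f for f in tied[0] if f in common], False
    smallest = min(tied, key=len)
    return list(smallest), True


class NestedLOOCVClassifier(BaseEstimator, ClassifierMixin):
    """Nested leave-one-out cross-validation around recursive feature selection.

    ``fit`` runs the outer LOOCV (each held-out case is scored by a model
    selected and trained without it), pools the out-of-fold probabilities
    into cross-validated AUC/sensitivity/specificity, resolves the final
    feature set by the tie-intersection rule, and retrains the final
    boosted-tree model on all training rows.

    Fitted attributes: ``classes_``, ``cv_metrics_``, ``oof_proba_``,
    ``fold_selections_``, ``selected_features_``, ``fallback_flag_``,
    ``inner_auc_by_size_folds_``, ``model_``.
    """

    def __init__(
        self,
        candidate_sizes: tuple = DEFAULT_CANDIDATE_SIZES,
        gbt_spec: GBTModelSpec | None = None,
        rf_trees: int = 150,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.candidate_sizes = candidate_sizes
        self.gbt_spec = gbt_spec
        self.rf_trees = rf_trees
        self.threshold = threshold
        self.seed = seed

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        y = np.asarray(y)
        if len(y) < 10:
            raise PartitionError("outer LOOCV needs at least 10 cases")
        self.classes_ = np.array(sorted(np.unique(y).tolist()))
        spec = self.gbt_spec or GBTModelSpec(seed=self.seed)
        n = len(y)
        oof = np.empty((n, len(self.classes_)))
        self.fold_selections_ = []
        self.inner_auc_by_size_folds_ = []
        for i in range(n):
            rest = np.arange(n) != i
            selector = RecursiveFeatureSelector(self.candidate_sizes, spec, self.rf_trees, self.seed)
            selector.fit(X.iloc[rest], y[rest])
            feats = selector.selected_features_
            model = train_gbt(X.iloc[rest][feats], y[rest], feats, spec)
            oof[i] = model.predict_proba(X.iloc[[i]][feats])[0]
            self.fold_selections_.append((tuple(feats), selector.inner_auc_))
            self.inner_auc_by_size_folds_.append(dict(selector.inner_auc_by_size_))
        self.oof_proba_ = oof
        if len(self.classes_) == 2:
            pos_idx = int(np.where(self.classes_ == POSITIVE_CLASS)[0][0]) if POSITIVE_CLASS in self.classes_ else 1
            self.cv_metrics_ = evaluate_binary(oof[:, pos_idx], y == self.classes_[pos_idx], self.threshold)
        else:
            self.cv_metrics_ = multiclass_metrics(oof, y, list(self.classes_))
        self.selected_features_, self.fallback_flag_ = final_feature_set(self.fold_selections_)
        self.model_ = train_gbt(X[self.selected_features_], y, self.selected_features_, spec)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        if isinstance(X, pd.DataFrame):
            X = X[self.selected_features_]
        else:
            raise ValueError("predict_proba requires a DataFrame with named features")
        return self.model_.predict_proba(X.to_numpy(dtype=np.float32))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def evaluate(self, X, y) -> dict[str, float]:
        """Test metrics of the final model on held-out data."""
        proba = self.predict_proba(X)
        y = np.asarray(y)
        if len(self.classes_) == 2:
            pos_idx = int(np.where(self.classes_ == POSITIVE_CLASS)[0][0]) if POSITIVE_CLASS in self.classes_ else 1
            return evaluate_binary(proba[:, pos_idx], y == self.classes_[pos_idx], self.threshold)
        return multiclass_metrics(proba, y, list(self.classes_))


# ---------------------------------------------------------------------------
# repetitions and the fractal ablation


@dataclass
class ModelRunResult:
    repetition: int
    target: str
    variant: str
    cv: dict
    test: dict
    selected_features: list
    n_train: int
    n_test: int
    seed: int
    inner_auc_by_size_folds: list = field(default_factory=list)


def run_repetitions(
    features: pd.DataFrame,
    labels: pd.Series,
    target: str = "",
    variant: str = "with_fractal",
    n_reps: int | None = None,
    n_range: tuple[int, int] = (10, 15),
    train_fraction: float = 0.75,
    candidate_sizes: tuple = DEFAULT_CANDIDATE_SIZES,
    gbt_spec: GBTModelSpec | None = None,
    rf_trees: int = 150,
    master_seed: int = 0,
) -> list[ModelRunResult]:
    """Repeat partition → nested selection/training → test evaluation.

    The number of repetitions is drawn uniformly from ``n_range`` unless
    fixed by ``n_reps``.  The ``without_fractal`` variant drops the
    fractal-map feature columns before the analysis.  Rows with missing
    labels must be excluded by the caller.
    """
    from .features import fractal_feature_subset

    rng = np.random.default_rng(master_seed)
    n = int(n_reps) if n_reps is not None else int(rng.integers(n_range[0], n_range[1] + 1))
    rep_seeds = rng.integers(0, 2**31 - 1, size=n)
    if variant == "without_fractal":
        drop = set(fractal_feature_subset(list(features.columns)))
        features = features[[c for c in features.columns if c not in drop]]
    elif variant != "with_fractal":
        raise ValueError(f"unknown variant {variant!r}")
    results = []
    ids = np.asarray(features.index)
    y = np.asarray(labels)
    for r in range(n):
        seed = int(rep_seeds[r])
        part = stratified_partition(ids, y, target, train_fraction, seed)
        tr = features.loc[part.train_ids]
        te = features.loc[part.test_ids]
        y_tr = labels.loc[part.train_ids].to_numpy()
        y_te = labels.loc[part.test_ids].to_numpy()
        spec = gbt_spec or GBTModelSpec(seed=seed)
        clf = NestedLOOCVClassifier(candidate_sizes, spec, rf_trees, seed=seed)
        clf.fit(tr, y_tr)
        results.append(
            ModelRunResult(
                repetition=r,
                target=target,
                variant=variant,
                cv=clf.cv_metrics_,
                test=clf.evaluate(te, y_te),
                selected_features=list(clf.selected_features_),
                n_train=len(part.train_ids),
                n_test=len(part.test_ids),
                seed=seed,
                inner_auc_by_size_folds=clf.inner_auc_by_size_folds_,
            )
        )
    return results


def summarize_runs(results: list[ModelRunResult]) -> pd.DataFrame:
    """Mean ± SD summary per (target, variant, metric block)."""
    rows = []
    for block in ("cv", "test"):
        for metric in ("auc", "sensitivity", "specificity", "accuracy", "multiclass_auc"):
            vals = [getattr(r, block).get(metric) for r in results if metric in getattr(r, block)]
            if vals:
                rows.append(
                    {
                        "block": block,
                        "metric": metric,
                        "n": len(vals),
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
    return pd.DataFrame(rows)
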