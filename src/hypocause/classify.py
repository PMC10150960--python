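"""Subject-grouped nested cross-validated cause classification.

The experiment design: an outer grouped 10-fold CV (subjects never split
across the train/validation boundary), and inside each outer training set a
grouped 5-fold plan used by SFFS — sequential forward floating selection —
whose candidate subsets are scored by the inner-CV mean F1 of an extremely
randomized trees classifier with inverse-frequency observation weights. The
selected subset then feeds a small dropout neural network
(:mod:`hypocause.nn`) trained per objective (F1 / recall / precision), and
per-class F1, recall, precision and MCC are measured on the outer validation
subjects. A variant runs the same selection over principal-component scores
instead of raw features.

All preprocessing (mean imputation, standardization, PCA) is fitted on the
outer training fold only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesClassifier

from .features import ADVISOR_FEATURES, FEATURE_REGISTRY
from .metrics import class_weights, evaluate_metrics, f1_recall_precision
from .nn import NNConfig, NeuralClassifier

__all__ = [
    "FoldPlan",
    "ClassifierSpec",
    "CVReport",
    "grouped_kfold",
    "sffs_select",
    "pca_transform",
    "fit_nn_classifier",
    "run_cv_experiment",
]

log = logging.getLogger(__name__)

CATEGORIES = ("ACTIVITY", "FOOD", "MEDICATION")


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Outer folds (train/validation subject sets) plus per-outer-fold nested
    inner plans; validation sets partition the subjects."""

    outer: list[tuple[frozenset, frozenset]]
    inner: list[list[tuple[frozenset, frozenset]]]
    seed: int


def _partition_subjects(
    subjects: np.ndarray, sizes: np.ndarray, k: int, rng: np.random.Generator
) -> list[set]:
    """Greedy balanced partition of subjects into k groups by episode count
    (largest-first into the currently lightest group; seeded shuffle breaks
    ties)."""
    order = rng.permutation(len(subjects))
    subjects, sizes = subjects[order], sizes[order]
    by_size = np.argsort(-sizes, kind="stable")
    groups: list[set] = [set() for _ in range(k)]
    totals = np.zeros(k)
    for i in by_size:
        g = int(np.argmin(totals))
        groups[g].add(subjects[i])
        totals[g] += sizes[i]
    return groups


def grouped_kfold(
    subject_ids: np.ndarray, k: int, seed: int, n_inner: int = 5
) -> FoldPlan:
    """Build the grouped k-fold plan from the per-episode subject id vector.

    Subjects are partitioned into k validation groups of near-equal episode
    counts; an analogous grouped ``n_inner``-fold plan is built on every
    outer training set. Deterministic for a given seed.
    """
    subject_ids = np.asarray(subject_ids)
    uniq, counts = np.unique(subject_ids, return_counts=True)
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(uniq)})")
    rng = np.random.default_rng(seed)
    groups = _partition_subjects(uniq, counts, k, rng)
    sizes = {s: c for s, c in zip(uniq, counts)}

    outer, inner = [], []
    for g in groups:
        val = frozenset(g)
        train = frozenset(set(uniq) - g)
        outer.append((train, val))
        tr = np.array(sorted(train))
        tr_sizes = np.array([sizes[s] for s in tr])
        n_in = min(n_inner, len(tr))
        sub = _partition_subjects(tr, tr_sizes, n_in, rng)
        inner.append(
            [(frozenset(set(tr) - s), frozenset(s)) for s in sub]
        )
    return FoldPlan(outer=outer, inner=inner, seed=seed)


# ---------------------------------------------------------------------------
# Preprocessing (train-fold statistics only)
# ---------------------------------------------------------------------------


class _Preprocessor:
    """Mean imputation + standardization fitted on the training fold."""

    def __init__(self, X_train: np.ndarray, standardize: bool) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.means = np.nanmean(X_train, axis=0)
        self.means = np.where(np.isfinite(self.means), self.means, 0.0)
        if standardize:
            Xi = self._impute(X_train)
            sd = Xi.std(axis=0)
            self.scale = np.where(sd > 0, sd, 1.0)
        else:
            self.scale = np.ones_like(self.means)

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        idx = np.where(~np.isfinite(X))
        X[idx] = np.take(self.means, idx[1])
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (self._impute(X) - self.means) / self.scale


def pca_transform(X_train: np.ndarray):
    """Fit mean-imputation + standardization + full PCA on the training fold;
    returns (components, transform function). Components are orthonormal and
    ordered by explained variance."""
    if X_train.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training rows")
    prep = _Preprocessor(X_train, standardize=True)
    Z = prep.transform(X_train)
    pca = PCA(svd_solver="full")
    pca.fit(Z)

    def transform(X: np.ndarray) -> np.ndarray:
        return pca.transform(prep.transform(X))

    return pca.components_, transform


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SFFSConfig:
    max_features: int = 20
    n_trees: int = 100
    n_inner_folds: int = 5
    #: consecutive non-improving forward additions tolerated before stopping
    #: (the returned subset is the best-scoring one observed, so a tolerated
    #: bad addition can still be floated out or discarded)
    patience: int = 1
    #: leaf-size regularization for the tree evaluator (keeps the trees
    #: shallow enough to be honest and cheap on a few hundred events)
    min_samples_leaf: int = 5


def _inner_cv_f1(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cols: list[int],
    inner_folds: list[tuple[frozenset, frozenset]],
    seed: int,
    n_trees: int,
    n_classes: int,
    min_samples_leaf: int = 5,
) -> float:
    """Mean F1 over the inner grouped folds of an extremely randomized trees
    classifier on the given feature columns (class-weighted samples). Binary
    problems score the positive class; multiclass the macro average."""
    scores = []
    for train_s, val_s in inner_folds:
        tr = np.isin(groups, list(train_s))
        va = np.isin(groups, list(val_s))
        if len(np.unique(y[tr])) < 2 or not va.any():
            continue
        w = class_weights(y[tr])
        sw = np.array([w[c] for c in y[tr]])
        clf = ExtraTreesClassifier(
            n_estimators=n_trees,
            min_samples_leaf=min_samples_leaf,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(X[np.ix_(tr, cols)], y[tr], sample_weight=sw)
        y_pred = clf.predict(X[np.ix_(va, cols)])
        if n_classes == 2:
            scores.append(f1_recall_precision(y[va], y_pred, classes=[1])[1]["f1"])
        else:
            per = f1_recall_precision(y[va], y_pred, classes=list(range(n_classes)))
            scores.append(float(np.mean([per[c]["f1"] for c in per])))
    return float(np.mean(scores)) if scores else -np.inf


def sffs_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    inner_folds: list[tuple[frozenset, frozenset]],
    seed: int,
    config: SFFSConfig = SFFSConfig(),
) -> list[int]:
    """Sequential forward floating selection of feature column indices.

    Forward: add the candidate maximizing the inner-CV mean F1. Floating:
    after each addition, repeatedly remove any member whose removal strictly
    improves on the best score previously recorded for the smaller subset
    size. Stops when no addition improves the criterion (never returning an
    empty set) or when ``max_features`` is reached. Deterministic given the
    seed; evaluator failures score a candidate at -inf.
    """
    n_features = X.shape[1]
    if n_features < 2:
        return list(range(n_features))
    n_classes = len(np.unique(y))

    def score(cols: list[int]) -> float:
        try:
            return _inner_cv_f1(
                X, y, groups, cols, inner_folds, seed, config.n_trees,
                n_classes, config.min_samples_leaf,
            )
        except Exception as exc:  # evaluator failure -> worst score, logged
            log.warning("SFFS evaluator failed on %s: %s", cols, exc)
            return -np.inf

    selected: list[int] = []
    best_at_size: dict[int, float] = {0: -np.inf}
    cache: dict[tuple, float] = {}

    def cached_score(cols: list[int]) -> float:
        key = tuple(sorted(cols))
        if key not in cache:
            cache[key] = score(cols)
        return cache[key]

    best_overall: tuple[float, list[int]] = (-np.inf, [])
    fails = 0
    while len(selected) < min(config.max_features, n_features):
        candidates = [j for j in range(n_features) if j not in selected]
        cand_scores = [cached_score(selected + [j]) for j in candidates]
        best_i = int(np.argmax(cand_scores))
        best_j, best_s = candidates[best_i], cand_scores[best_i]
        selected.append(best_j)
        best_at_size[len(selected)] = max(
            best_s, best_at_size.get(len(selected), -np.inf)
        )

        # floating removal: drop members (not the one just added) while that
        # strictly improves the best known score at the smaller size
        improved = True
        while improved and len(selected) > 2:
            improved = False
            removal_scores = [
                (cached_score([c for c in selected if c != r]), r)
                for r in selected[:-1]
            ]
            s_best, r_best = max(removal_scores, key=lambda t: t[0])
            if s_best > best_at_size.get(len(selected) - 1, -np.inf) + 1e-12:
                selected.remove(r_best)
                best_at_size[len(selected)] = s_best
                improved = True

        current = cached_score(selected)
        if current > best_overall[0] + 1e-12:
            best_overall = (current, list(selected))
            fails = 0
        else:
            fails += 1
            if fails > config.patience:
                break
    return best_overall[1] if best_overall[1] else selected


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierSpec:
    """One experiment cell: scenario x feature space x training objective."""

    scenario: str = "multiclass"  # 'ovr:ACTIVITY' | 'ovr:FOOD' | 'ovr:MEDICATION' | 'multiclass'
    feature_space: str = "raw"  # 'raw' | 'pca'
    objective: str = "f1"  # 'f1' | 'recall' | 'precision'
    k_outer: int = 10
    sffs: SFFSConfig = field(default_factory=SFFSConfig)
    nn: NNConfig = field(default_factory=NNConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        valid = {"multiclass"} | {f"ovr:{c}" for c in CATEGORIES}
        if self.scenario not in valid:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.feature_space not in ("raw", "pca"):
            raise ValueError(f"unknown feature space {self.feature_space!r}")


@dataclass
class CVReport:
    """Fold-level and aggregated metrics for one experiment cell."""

    spec: ClassifierSpec
    fold_metrics: pd.DataFrame  # fold, class, f1, recall, precision, mcc
    selected_features: list[list[str]]
    skipped_folds: list[int]
    predictions: pd.DataFrame | None = None  # fold, episode_id, y_true, y_pred

    def summary(self) -> pd.DataFrame:
        """mean +/- sample SD (ddof=1) across folds, per class."""
        g = self.fold_metrics.groupby("class")[["f1", "recall", "precision", "mcc"]]
        mean, sd = g.mean(), g.std(ddof=1).fillna(0.0)
        rows = []
        for cls in mean.index:
            for m in ("f1", "recall", "precision", "mcc"):
                rows.append(
                    {
                        "scenario": self.spec.scenario,
                        "feature_space": self.spec.feature_space,
                        "objective": self.spec.objective,
                        "class": cls,
                        "metric": m,
                        "mean": float(mean.loc[cls, m]),
                        "sd": float(sd.loc[cls, m]),
                    }
                )
        return pd.DataFrame(rows)


def fit_nn_classifier(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    groups: np.ndarray,
    n_classes: int,
    objective: str,
    seed: int,
    nn_config: NNConfig = NNConfig(),
) -> NeuralClassifier:
    """Train the dropout MLP on preprocessed features (see module docstring
    of :mod:`hypocause.nn` for the selection protocol)."""
    cfg = replace(nn_config, objective=objective)
    clf = NeuralClassifier(n_classes=n_classes, config=cfg, seed=seed)
    return clf.fit(X, y, sample_weight=sample_weight, groups=groups)


def _encode_labels(categories: np.ndarray, scenario: str) -> tuple[np.ndarray, list[str], int]:
    if scenario == "multiclass":
        mapping = {c: i for i, c in enumerate(CATEGORIES)}
        return np.array([mapping[c] for c in categories]), list(CATEGORIES), 3
    positive = scenario.split(":", 1)[1]
    return (categories == positive).astype(int), ["rest", positive], 2


def run_cv_experiment(
    features: pd.DataFrame,
    spec: ClassifierSpec,
    folds: list[int] | None = None,
) -> CVReport:
    """Run one scenario end to end on a feature table (canonical columns of
    the event representation; advisor features are excluded up front to keep
    the sample, mirroring the multiple-regression arm).

    Per outer fold: fit imputation/standardization (and PCA if requested) on
    the training subjects, run SFFS with the inner grouped plan, train the
    neural classifier with inverse-frequency weights, and measure per-class
    metrics on the held-out subjects. Folds whose training side misses a
    class are skipped with a warning and recorded in the report.
    """
    cols = [c for c in FEATURE_REGISTRY if c in features.columns and c not in ADVISOR_FEATURES]
    X_all = features[cols].to_numpy(dtype=float)
    groups_all = features["subject_id"].to_numpy()
    y_all, class_names, n_classes = _encode_labels(
        features["category"].to_numpy(), spec.scenario
    )

    plan = grouped_kfold(groups_all, spec.k_outer, spec.seed)
    fold_rows, selections, skipped, pred_rows = [], [], [], []

    for fold_id, ((train_s, val_s), inner_folds) in enumerate(zip(plan.outer, plan.inner)):
        if folds is not None and fold_id not in folds:
            continue
        tr = np.isin(groups_all, list(train_s))
        va = np.isin(groups_all, list(val_s))
        y_tr, y_va = y_all[tr], y_all[va]
        if len(np.unique(y_tr)) < n_classes or not va.any():
            log.warning("fold %d skipped: missing class in training or empty validation", fold_id)
            skipped.append(fold_id)
            continue

        prep = _Preprocessor(X_all[tr], standardize=True)
        Z_tr, Z_va = prep.transform(X_all[tr]), prep.transform(X_all[va])
        if spec.feature_space == "pca":
            _, apply_pca = pca_transform(X_all[tr])
            Z_tr, Z_va = apply_pca(X_all[tr]), apply_pca(X_all[va])
            names = [f"PC{i + 1}" for i in range(Z_tr.shape[1])]
        else:
            names = cols

        sel = sffs_select(
            Z_tr, y_tr, groups_all[tr], inner_folds,
            seed=spec.seed + fold_id, config=spec.sffs,
        )
        selections.append([names[j] for j in sel])

        w = class_weights(y_tr)
        sw = np.array([w[c] for c in y_tr])
        clf = fit_nn_classifier(
            Z_tr[:, sel], y_tr, sw, groups_all[tr],
            n_classes=n_classes, objective=spec.objective,
            seed=spec.seed + 1000 + fold_id, nn_config=spec.nn,
        )
        y_pred = clf.predict(Z_va[:, sel])
        for eid, yt, yp in zip(features["episode_id"].to_numpy()[va], y_va, y_pred):
            pred_rows.append(
                {"fold": fold_id, "episode_id": eid, "y_true": int(yt), "y_pred": int(yp)}
            )

        report_classes = list(range(n_classes)) if n_classes == 3 else [1]
        res = evaluate_metrics(y_va, y_pred, classes=report_classes)
        for c in report_classes:
            fold_rows.append(
                {
                    "fold": fold_id,
                    "class": class_names[c],
                    **res["per_class"][c],
                }
            )

    fm = pd.DataFrame(fold_rows, columns=["fold", "class", "precision", "recall", "f1", "mcc"])
    preds = pd.DataFrame(pred_rows, columns=["fold", "episode_id", "y_true", "y_pred"])
    return CVReport(
        spec=spec,
        fold_metrics=fm,
        selected_features=selections,
        skipped_folds=skipped,
        predictions=preds,
    )
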