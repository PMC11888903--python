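"""Experiment harness: splitting, scaling, tuning, metrics, trials.

The protocol mirrors a standard tuned-comparison study.  Per trial:

1. stratified 90/10 train-test split (largest-remainder per-class counts);
2. standard scaling (fit on training data only);
3. random-search hyperparameter tuning, 20 iterations scored by mean
   accuracy over stratified 5-fold cross-validation, with the scaler refit
   inside every fold on the training folds only (no leakage);
4. refit on the full training set with the winning combination and
   evaluation on the held-out test set: macro precision, recall, F1 and
   specificity plus overall accuracy, all derived from the one-vs-rest
   confusion counts.

Baseline classifiers (SVM, RF, KNN, LDA, CART) are delegated to
scikit-learn behind a uniform train/predict contract; PHCA is the bespoke
member of the roster.  Trial ``t`` of a run uses seed ``base_seed + t`` for
its split, sampler and fold shuffling, so reruns are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .classifier import HomologyDimensionChoice, PHCAClassifier

__all__ = [
    "LabelledDataset",
    "ScalerParams",
    "SearchSpace",
    "MetricsReport",
    "TrialReport",
    "ExperimentConfig",
    "METRIC_NAMES",
    "DEFAULT_ROSTER",
    "stratified_split",
    "fit_scaler",
    "apply_scaler",
    "build_classifier",
    "default_search_space",
    "random_search_cv",
    "evaluate",
    "misclassification_report",
    "run_trials",
    "aggregate_trials",
]

logger = logging.getLogger("phca")

METRIC_NAMES = ("precision", "recall", "f1", "specificity", "accuracy")
DEFAULT_ROSTER = ("PHCA", "SVM", "RF", "KNN", "LDA", "CART")


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelledDataset:
    """Feature table with labels and an ordered class catalogue."""

    features: np.ndarray
    labels: np.ndarray
    class_catalogue: tuple

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if feats.ndim != 2:
            raise ValueError("features must be a 2-d table")
        if len(feats) != len(labels):
            raise ValueError("features and labels disagree in length")
        if len(feats) < 1:
            raise ValueError("dataset must contain at least one row")
        if not np.isfinite(feats).all():
            raise ValueError("features contain missing or non-finite values")
        catalogue = tuple(self.class_catalogue)
        missing = set(labels.tolist()) - set(catalogue)
        if missing:
            raise ValueError(f"labels outside the class catalogue: {sorted(map(str, missing))}")
        feats.setflags(write=False)
        labels.setflags(write=False)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_catalogue", catalogue)

    @classmethod
    def from_arrays(cls, X, y, catalogue: Optional[Sequence] = None) -> "LabelledDataset":
        y = np.asarray(y)
        if catalogue is None:
            # first-appearance order keeps catalogue deterministic in row order
            _, idx = np.unique(y, return_index=True)
            catalogue = tuple(y[np.sort(idx)].tolist())
        return cls(np.asarray(X, dtype=float), y, tuple(catalogue))

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.labels == c)) for c in self.class_catalogue}

    def subset(self, indices: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(self.features[indices], self.labels[indices], self.class_catalogue)

    def to_frame(self, feature_prefix: str = "f") -> pd.DataFrame:
        cols = [f"{feature_prefix}{j}" for j in range(self.n_features)]
        frame = pd.DataFrame(self.features, columns=cols)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "id", np.arange(self.n_rows))
        return frame


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------


def _largest_remainder_counts(class_sizes: Sequence[int], fraction: float) -> list[int]:
    """Per-class test counts: floor the ideal counts, then hand the remaining
    rows to the classes with the largest fractional parts so the overall
    total equals round(n * fraction)."""
    ideal = [s * fraction for s in class_sizes]
    base = [int(np.floor(x)) for x in ideal]
    total = int(round(sum(class_sizes) * fraction))
    short = total - sum(base)
    remainders = sorted(range(len(ideal)), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in remainders[:max(short, 0)]:
        base[i] += 1
    return base


def stratified_split(data: LabelledDataset, test_fraction: float, seed: int):
    """Split into disjoint, exhaustive train/test sets with per-class counts
    proportional to ``test_fraction`` (largest-remainder rounding).

    Within each class rows are put in a canonical (lexicographic) order
    before the seeded shuffle, so the partition of the row *multiset* does
    not depend on the input row order.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    counts = data.class_counts()
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"classes with fewer than 2 rows cannot be split: {thin}")
    sizes = [counts[c] for c in data.class_catalogue]
    test_counts = _largest_remainder_counts(sizes, test_fraction)
    rng = np.random.default_rng(seed)
    test_idx, train_idx = [], []
    for c, t in zip(data.class_catalogue, test_counts):
        idx = np.flatnonzero(data.labels == c)
        canonical = idx[np.lexsort(data.features[idx].T)]
        perm = rng.permutation(len(canonical))
        shuffled = canonical[perm]
        test_idx.append(shuffled[:t])
        train_idx.append(shuffled[t:])
    test_idx = np.concatenate(test_idx)
    train_idx = np.concatenate(train_idx)
    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))


# ---------------------------------------------------------------------------
# standard scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature mean/std from training data; zero-variance features are
    centered but not divided."""

    mean: np.ndarray
    std: np.ndarray


def fit_scaler(train: LabelledDataset) -> ScalerParams:
    feats = train.features
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)  # population std, matching the usual scaler
    return ScalerParams(mean, np.where(std > 0, std, 1.0))


def apply_scaler(params: ScalerParams, data: LabelledDataset) -> LabelledDataset:
    scaled = (data.features - params.mean) / params.std
    return LabelledDataset(scaled, data.labels, data.class_catalogue)


def _scale_arrays(train_X: np.ndarray, other_X: np.ndarray):
    mean = train_X.mean(axis=0)
    std = train_X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (train_X - mean) / std, (other_X - mean) / std


# ---------------------------------------------------------------------------
# classifier roster and hyperparameter space
# ---------------------------------------------------------------------------


def build_classifier(classifier_id: str, params: dict, seed: int = 0):
    """Instantiate a roster member with a concrete hyperparameter draw."""
    p = dict(params)
    if classifier_id == "PHCA":
        return PHCAClassifier(**p)
    if classifier_id == "SVM":
        return SVC(kernel="rbf", random_state=seed, **p)
    if classifier_id == "RF":
        return RandomForestClassifier(random_state=seed, **p)
    if classifier_id == "KNN":
        return KNeighborsClassifier(**p)
    if classifier_id == "LDA":
        solver = p.get("solver", "svd")
        # shrinkage is incompatible with the svd solver; the draw is dropped
        if solver == "svd":
            p.pop("shrinkage", None)
        return LinearDiscriminantAnalysis(**p)
    if classifier_id == "CART":
        return DecisionTreeClassifier(random_state=seed, **p)
    raise KeyError(f"unknown classifier id {classifier_id!r}")


def _sample_svm(rng):
    return {"C": float(rng.uniform(2.0 ** -3, 2.0 ** 15)),
            "gamma": str(rng.choice(["auto", "scale"]))}


def _sample_rf(rng):
    return {"n_estimators": int(rng.integers(1, 351)),
            "max_depth": int(rng.integers(1, 6)),
            "min_samples_split": int(rng.integers(2, 11))}


def _sample_knn(rng):
    return {"n_neighbors": int(rng.integers(1, 501))}


def _sample_lda(rng):
    return {"solver": str(rng.choice(["svd", "lsqr", "eigen"])),
            "shrinkage": float(rng.uniform(0.0, 1.0))}


def _sample_cart(rng):
    return {"max_depth": int(rng.integers(1, 31)),
            "min_samples_leaf": int(rng.integers(1, 61)),
            "min_samples_split": int(rng.integers(2, 61))}


def _sample_phca(rng):
    return {"homology_dimension": str(rng.choice(["H0_ONLY", "H1_ONLY", "H0_AND_H1"]))}


@dataclass(frozen=True)
class SearchSpace:
    """Per-classifier hyperparameter samplers (callable(rng) -> params)."""

    samplers: dict

    def sample(self, classifier_id: str, rng: np.random.Generator) -> dict:
        return self.samplers[classifier_id](rng)


def default_search_space() -> SearchSpace:
    """The study's tuning grid: SVM C~U(2^-3, 2^15) with rbf kernel and
    gamma in {auto, scale}; RF n_estimators 1-350, max_depth 1-5,
    min_samples_split 2-10; KNN n_neighbors 1-500 (clamped to the training
    size at fit); LDA solver in {svd, lsqr, eigen} with shrinkage~U(0,1)
    (dropped for svd); CART max_depth 1-30, min_samples_leaf 1-60,
    min_samples_split 2-60; PHCA homology dimension in {H0, H1, H0+H1}."""
    return SearchSpace({
        "SVM": _sample_svm,
        "RF": _sample_rf,
        "KNN": _sample_knn,
        "LDA": _sample_lda,
        "CART": _sample_cart,
        "PHCA": _sample_phca,
    })


def _fit_predict(classifier_id: str, params: dict, seed: int,
                 train_X, train_y, test_X) -> np.ndarray:
    p = dict(params)
    if classifier_id == "KNN":
        p["n_neighbors"] = min(p["n_neighbors"], len(train_y))
    clf = build_classifier(classifier_id, p, seed)
    clf.fit(train_X, train_y)
    return np.asarray(clf.predict(test_X))


def random_search_cv(classifier_id: str, space: SearchSpace, train: LabelledDataset,
                     n_iter: int = 20, folds: int = 5, seed: int = 0):
    """Random search scored by mean stratified-CV accuracy.

    For each sampled combination the training set is split into ``folds``
    stratified folds; the scaler is refit on the training folds only.  The
    first-sampled combination among ties wins.  Returns
    ``(best_params, best_mean_accuracy)``.
    """
    counts = train.class_counts()
    thin = [c for c, n in counts.items() if n < folds]
    if thin:
        raise ValueError(f"classes with fewer than {folds} rows cannot be cross-validated: {thin}")
    rng = np.random.default_rng(seed)
    candidates = [space.sample(classifier_id, rng) for _ in range(n_iter)]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2 ** 32))
    fold_indices = list(skf.split(train.features, train.labels))
    best_params, best_score = None, -np.inf
    seen: dict = {}   # scoring is deterministic, so repeated draws share a score
    for params in candidates:
        key = tuple(sorted(params.items()))
        if key in seen:
            continue
        accs = []
        for tr, va in fold_indices:
            tr_X, va_X = _scale_arrays(train.features[tr], train.features[va])
            pred = _fit_predict(classifier_id, params, seed, tr_X, train.labels[tr], va_X)
            accs.append(float(np.mean(pred == train.labels[va])))
        seen[key] = score = float(np.mean(accs))
        if score > best_score:
            best_params, best_score = params, score
    return best_params, best_score


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    """One-vs-rest counts, macro metrics and the raw confusion matrix.

    ``confusion[i, j]`` counts rows of true class ``catalogue[i]`` predicted
    as ``catalogue[j]``.
    """

    catalogue: tuple
    confusion: np.ndarray
    per_class: pd.DataFrame      # columns TP, FP, FN, TN, precision, recall, f1, specificity
    precision: float
    recall: float
    f1: float
    specificity: float
    accuracy: float

    def metric(self, name: str) -> float:
        return float(getattr(self, name))

    def as_dict(self) -> dict:
        return {m: self.metric(m) for m in METRIC_NAMES}


def evaluate(true_labels, predicted_labels, catalogue) -> MetricsReport:
    """Macro-averaged precision/recall/F1/specificity and overall accuracy.

    Per-class scores come from the one-vs-rest confusion counts; a class
    with undefined precision or recall contributes 0 to the macro average,
    while undefined specificity (a class with no negative instances) counts
    as vacuously 1.  Accuracy is correct/total over the whole set.
    """
    true = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if true.shape != pred.shape:
        raise ValueError("true and predicted label lists differ in length")
    if len(true) < 1:
        raise ValueError("cannot evaluate an empty prediction list")
    catalogue = tuple(catalogue)
    pos = {c: i for i, c in enumerate(catalogue)}
    conf = np.zeros((len(catalogue), len(catalogue)), dtype=int)
    for t, p in zip(true.tolist(), pred.tolist()):
        conf[pos[t], pos[p]] += 1
    total = conf.sum()
    rows = []
    for i, c in enumerate(catalogue):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        tn = total - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
        # no negative instances at all: vacuously perfect rejection
        specificity = tn / (tn + fp) if tn + fp else 1.0
        rows.append((c, tp, fp, fn, tn, precision, recall, f1, specificity))
    per_class = pd.DataFrame(rows, columns=["class", "TP", "FP", "FN", "TN",
                                            "precision", "recall", "f1", "specificity"])
    per_class = per_class.set_index("class")
    return MetricsReport(
        catalogue=catalogue,
        confusion=conf,
        per_class=per_class,
        precision=float(per_class["precision"].mean()),
        recall=float(per_class["recall"].mean()),
        f1=float(per_class["f1"].mean()),
        specificity=float(per_class["specificity"].mean()),
        accuracy=float(np.trace(conf) / total),
    )


def misclassification_report(report: Union[MetricsReport, np.ndarray],
                             catalogue: Optional[Sequence] = None) -> list[tuple]:
    """Off-diagonal confusion cells ranked by count (desc), ties by label order.

    Accepts a :class:`MetricsReport` or a raw (cumulative) confusion matrix
    with its catalogue, so per-trial matrices can be summed element-wise and
    analyzed jointly.
    """
    if isinstance(report, MetricsReport):
        conf, catalogue = report.confusion, report.catalogue
    else:
        conf = np.asarray(report)
        if catalogue is None:
            raise ValueError("catalogue required with a raw confusion matrix")
    catalogue = tuple(catalogue)
    cells = []
    for i, t in enumerate(catalogue):
        for j, p in enumerate(catalogue):
            if i != j and conf[i, j] > 0:
                cells.append((t, p, int(conf[i, j]), i, j))
    cells.sort(key=lambda c: (-c[2], c[3], c[4]))
    return [(t, p, n) for t, p, n, *_ in cells]


# ---------------------------------------------------------------------------
# trial orchestration
# ---------------------------------------------------------------------------


@dataclass
class TrialReport:
    trial_index: int
    seed: int
    chosen_params: dict          # classifier id -> params
    cv_scores: dict              # classifier id -> mean CV accuracy
    metrics: dict                # classifier id -> MetricsReport


@dataclass
class ExperimentConfig:
    """Configuration for :func:`run_trials`.

    ``dataset`` is either a :class:`LabelledDataset` or a callable
    ``seed -> LabelledDataset`` (fresh draw per trial).  An optional
    ``per_trial_transform(dataset, seed)`` runs before the split (e.g. a
    balanced per-class subsample re-drawn with the trial seed).
    """

    dataset: Union[LabelledDataset, Callable[[int], LabelledDataset]]
    roster: Sequence[str] = DEFAULT_ROSTER
    n_trials: int = 10
    test_fraction: float = 0.1
    n_iter: int = 20
    folds: int = 5
    base_seed: int = 0
    search_space: SearchSpace = field(default_factory=default_search_space)
    per_trial_transform: Optional[Callable[[LabelledDataset, int], LabelledDataset]] = None


def run_trials(config: ExperimentConfig) -> list[TrialReport]:
    """Execute the full per-trial pipeline for every trial in the config.

    Trial ``t`` uses seed ``base_seed + t`` throughout (split, fold
    shuffling, hyperparameter sampling).
    """
    reports = []
    for t in range(config.n_trials):
        seed = config.base_seed + t
        t0 = time.perf_counter()
        try:
            data = config.dataset(seed) if callable(config.dataset) else config.dataset
            if config.per_trial_transform is not None:
                data = config.per_trial_transform(data, seed)
            train, test = stratified_split(data, config.test_fraction, seed)
            scaler = fit_scaler(train)
            train_s = apply_scaler(scaler, train)
            test_s = apply_scaler(scaler, test)
            chosen, cv_scores, metrics = {}, {}, {}
            for cid in config.roster:
                ts = time.perf_counter()
                params, score = random_search_cv(
                    cid, config.search_space, train, n_iter=config.n_iter,
                    folds=config.folds, seed=seed)
                pred = _fit_predict(cid, params, seed, train_s.features,
                                    train_s.labels, test_s.features)
                metrics[cid] = evaluate(test_s.labels, pred, data.class_catalogue)
                chosen[cid], cv_scores[cid] = params, score
                logger.info("trial %d %s: cv=%.4f test_acc=%.4f params=%s (%.1fs)",
                            t, cid, score, metrics[cid].accuracy, params,
                            time.perf_counter() - ts)
        except Exception as exc:
            raise RuntimeError(f"trial {t} failed: {exc}") from exc
        logger.info("trial %d done in %.1fs (seed=%d, n=%d)",
                    t, time.perf_counter() - t0, seed, data.n_rows)
        reports.append(TrialReport(t, seed, chosen, cv_scores, metrics))
    return reports


def trials_table(reports: Sequence[TrialReport]) -> pd.DataFrame:
    """Long-format table: one row per trial x classifier x metric."""
    rows = []
    for r in reports:
        for cid, m in r.metrics.items():
            for name in METRIC_NAMES:
                rows.append((r.trial_index, cid, name, m.metric(name)))
    return pd.DataFrame(rows, columns=["trial", "classifier", "metric", "value"])


def aggregate_trials(reports: Sequence[TrialReport]) -> pd.DataFrame:
    """Mean, min, max and IQR of every metric per classifier across trials."""
    table = trials_table(reports)
    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1
    agg = table.groupby(["classifier", "metric"])["value"].agg(
        mean="mean", min="min", max="max", iqr=iqr)
    return agg.reset_index()


def cumulative_confusion(reports: Sequence[TrialReport], classifier_id: str) -> np.ndarray:
    """Element-wise sum of a classifier's per-trial confusion matrices."""
    mats = [r.metrics[classifier_id].confusion for r in reports]
    return np.sum(mats, axis=0)


def write_outputs(reports: Sequence[TrialReport], out_dir: Union[str, Path]) -> dict:
    """Write trials.csv, cumulative confusion CSVs and chosen_params.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = trials_table(reports)
    table.to_csv(out / "trials.csv", index=False, float_format="%.17g")
    roster = list(reports[0].metrics) if reports else []
    for cid in roster:
        conf = cumulative_confusion(reports, cid)
        catalogue = reports[0].metrics[cid].catalogue
        frame = pd.DataFrame(conf, index=list(catalogue), columns=list(catalogue))
        frame.to_csv(out / f"confusion_{cid}.csv")
    chosen = {str(r.trial_index): {cid: {k: (v.name if hasattr(v, "name") else v)
                                         for k, v in params.items()}
                                   for cid, params in r.chosen_params.items()}
              for r in reports}
    (out / "chosen_params.json").write_text(json.dumps(chosen, indent=2, sort_keys=True))
    return {"trials": out / "trials.csv", "chosen_params": out / "chosen_params.json"}
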