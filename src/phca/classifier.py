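"""The persistent-homology classification algorithm (PHCA).

Training computes, for every class ``i``, the persistence diagram of its
point cloud ``X_i`` (under the auto horizon, half the class diameter) and
caches the total lifespan over the active homology dimensions.  To classify
a query ``alpha``, the classifier forms ``Y_i = X_i ∪ {alpha}`` for each
class, recomputes persistence of ``Y_i`` under ``Y_i``'s own auto horizon,
and scores the class by the absolute change in total lifespan:

    Score(X_i) = | Σ lifespans 𝒫(Y_i)  −  Σ lifespans 𝒫(X_i) |.

The query is assigned to the class of minimum score — the class whose
topology the query disturbs least — with ties broken by training-declared
label order (first wins).

With only dimension-0 homology active (the default, and the setting that
wins validation in practice) the totals have a minimum-spanning-tree closed
form and the fast single-linkage path is used; any setting involving
dimension 1 runs the general Vietoris-Rips engine.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .persistence import (
    FiltrationParams,
    PointCloud,
    h0_persistence_mst,
    total_lifespan,
    vr_persistence,
)

__all__ = [
    "HomologyDimensionChoice",
    "PHCAModel",
    "fit",
    "score_class",
    "predict_one",
    "predict",
    "save_model",
    "load_model",
    "PHCAClassifier",
]


class HomologyDimensionChoice(enum.Enum):
    """Which homology dimensions enter the lifespan totals."""

    H0_ONLY = "H0"
    H1_ONLY = "H1"
    H0_AND_H1 = "H0+H1"

    @property
    def dims(self) -> frozenset:
        return {
            HomologyDimensionChoice.H0_ONLY: frozenset({0}),
            HomologyDimensionChoice.H1_ONLY: frozenset({1}),
            HomologyDimensionChoice.H0_AND_H1: frozenset({0, 1}),
        }[self]


@dataclass
class PHCAModel:
    """Fitted PHCA state: per-class training clouds and baseline totals."""

    class_labels: list
    class_clouds: dict
    baseline_totals: dict
    dims: frozenset
    filtration: FiltrationParams = field(default_factory=FiltrationParams)
    # cached per-class condensed distances; rebuilt on demand, never serialized
    _class_dmat: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def feature_dim(self) -> int:
        return next(iter(self.class_clouds.values())).dim

    def class_distances(self, label) -> np.ndarray:
        """Square pairwise-distance matrix of a class cloud (cached)."""
        if label not in self._class_dmat:
            pts = self.class_clouds[label].points
            self._class_dmat[label] = squareform(pdist(pts)) if len(pts) > 1 else np.zeros((len(pts),) * 2)
        return self._class_dmat[label]


def _class_total(cloud: PointCloud, dims: frozenset, filtration: FiltrationParams) -> float:
    if dims == frozenset({0}):
        diagram = h0_persistence_mst(cloud)
    else:
        diagram = vr_persistence(cloud, filtration)
    return total_lifespan(diagram, dims)


def fit(train, choice: HomologyDimensionChoice = HomologyDimensionChoice.H0_ONLY) -> PHCAModel:
    """Fit PHCA: cache each class cloud and its baseline lifespan total.

    ``train`` is a :class:`~phca.evaluation.LabelledDataset` (or any object
    with ``features``, ``labels`` and ``class_catalogue``).  Every class in
    the catalogue must contribute at least one row.  Fitting is
    deterministic.
    """
    features = np.asarray(train.features, dtype=float)
    if features.size and not np.isfinite(features).all():
        raise ValueError("training features contain non-finite values")
    labels = np.asarray(train.labels)
    filtration = FiltrationParams(max_dimension=max(choice.dims), max_scale="auto")
    clouds, totals = {}, {}
    for label in train.class_catalogue:
        mask = labels == label
        if not mask.any():
            raise ValueError(f"class {label!r} has no training rows")
        cloud = PointCloud(features[mask])
        clouds[label] = cloud
        totals[label] = _class_total(cloud, choice.dims, filtration)
    return PHCAModel(list(train.class_catalogue), clouds, totals, choice.dims, filtration)


def _mst_total_with_query(model: PHCAModel, label, query: np.ndarray) -> float:
    """H0 total lifespan of X_i ∪ {query} from the augmented distance matrix."""
    cloud = model.class_clouds[label]
    n = cloud.n_points
    d_new = cdist(cloud.points, query[None, :]).ravel()
    dmat = np.zeros((n + 1, n + 1))
    dmat[:n, :n] = model.class_distances(label)
    dmat[:n, n] = d_new
    dmat[n, :n] = d_new
    horizon = float(dmat.max()) / 2.0
    if n == 0:
        return 0.0
    from scipy.sparse.csgraph import minimum_spanning_tree

    tree = minimum_spanning_tree(dmat + 1.0 - np.eye(n + 1))
    mst_sum = float(np.sum(tree.data - 1.0))
    return horizon + mst_sum / 2.0


def score_class(model: PHCAModel, label, query: Union[Sequence, np.ndarray]) -> float:
    """Absolute lifespan change when ``query`` joins class ``label``.

    The horizon of the augmented cloud ``Y_i`` is recomputed from ``Y_i``
    itself (half its diameter), not frozen from the training cloud.
    """
    if label not in model.class_clouds:
        raise KeyError(f"unknown class label {label!r}")
    q = np.atleast_1d(np.asarray(query, dtype=float))
    if q.shape[0] != model.feature_dim:
        raise ValueError(
            f"query has dimension {q.shape[0]}, model expects {model.feature_dim}"
        )
    if not np.isfinite(q).all():
        raise ValueError("query contains non-finite values")
    if model.dims == frozenset({0}):
        total_y = _mst_total_with_query(model, label, q)
    else:
        y_cloud = model.class_clouds[label].with_point(q)
        total_y = total_lifespan(vr_persistence(y_cloud, model.filtration), model.dims)
    return abs(total_y - model.baseline_totals[label])


def predict_one(model: PHCAModel, query: Union[Sequence, np.ndarray]):
    """Label minimizing the lifespan-change score; first label wins ties."""
    best_label, best_score = None, np.inf
    for label in model.class_labels:
        s = score_class(model, label, query)
        if s < best_score:
            best_label, best_score = label, s
    return best_label


def predict(model: PHCAModel, queries) -> list:
    """Row-wise :func:`predict_one` over a feature table (order-preserving)."""
    arr = np.asarray(getattr(queries, "values", queries), dtype=float)
    if arr.size == 0:
        return []
    arr = np.atleast_2d(arr)
    out = []
    for i, row in enumerate(arr):
        try:
            out.append(predict_one(model, row))
        except Exception as exc:
            raise type(exc)(f"query row {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# model persistence: JSON sidecar + per-class cloud CSVs
# ---------------------------------------------------------------------------


def save_model(model: PHCAModel, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "class_labels": [str(l) for l in model.class_labels],
        "dims": sorted(model.dims),
        "max_dimension": model.filtration.max_dimension,
        "max_scale": model.filtration.max_scale,
        "baseline_totals": {str(l): model.baseline_totals[l] for l in model.class_labels},
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    for i, label in enumerate(model.class_labels):
        pts = model.class_clouds[label].points
        header = ",".join(f"f{j}" for j in range(pts.shape[1]))
        np.savetxt(directory / f"class_{i}.csv", pts, delimiter=",",
                   header=header, comments="", fmt="%.17g")


def load_model(directory: Union[str, Path]) -> PHCAModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    labels = meta["class_labels"]
    clouds = {}
    for i, label in enumerate(labels):
        pts = np.loadtxt(directory / f"class_{i}.csv", delimiter=",", skiprows=1, ndmin=2)
        clouds[label] = PointCloud(pts)
    filtration = FiltrationParams(max_dimension=meta["max_dimension"], max_scale=meta["max_scale"])
    totals = {l: float(meta["baseline_totals"][l]) for l in labels}
    return PHCAModel(labels, clouds, totals, frozenset(meta["dims"]), filtration)


# ---------------------------------------------------------------------------
# sklearn-style adapter (uniform train/predict contract for the harness)
# ---------------------------------------------------------------------------


class PHCAClassifier:
    """Thin fit/predict wrapper so PHCA plugs into the evaluation harness.

    Parameters
    ----------
    homology_dimension:
        A :class:`HomologyDimensionChoice` (or its name), tuned like any
        other hyperparameter.
    """

    def __init__(self, homology_dimension: Union[HomologyDimensionChoice, str] = HomologyDimensionChoice.H0_ONLY):
        if isinstance(homology_dimension, str):
            homology_dimension = HomologyDimensionChoice[homology_dimension]
        self.homology_dimension = homology_dimension
        self.model_: Optional[PHCAModel] = None

    def get_params(self, deep: bool = True) -> dict:
        return {"homology_dimension": self.homology_dimension}

    def set_params(self, **params) -> "PHCAClassifier":
        for k, v in params.items():
            setattr(self, k, HomologyDimensionChoice[v] if isinstance(v, str) else v)
        return self

    def fit(self, X, y) -> "PHCAClassifier":
        from .evaluation import LabelledDataset

        self.model_ = fit(LabelledDataset.from_arrays(X, y), self.homology_dimension)
        return self

    def predict(self, X) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return np.asarray(predict(self.model_, X))
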