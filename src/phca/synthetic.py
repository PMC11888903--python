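"""Synthetic landmark-style datasets and geometric fixture clouds.

Two dataset families emulate the post-extraction form of a static
sign-alphabet image corpus (k classes of 63-dimensional feature vectors:
21 hand landmarks x (x, y, z)):

* Gaussian blobs (:func:`make_gaussian_classes`) — isotropic classes at
  mutually equidistant centers; the simplest stand-in with controllable
  between/within separation.
* Hand-like clouds (:func:`make_hand_like`) — per-class stylized hand
  skeletons (a wrist plus five finger chains of four joints) with
  per-sample jitter, random translation/scale, and a per-class probability
  that a sample fails landmark conversion and is excluded from the dataset
  but counted in the conversion report, mirroring how an image-to-landmark
  front-end drops undetected hands.

Default hand-like conditions follow the study corpus shape: 24 static
letter classes (A-Y excluding J, Z) of 450 samples each, with two classes
fully converted, two with markedly reduced conversion and a small failure
rate elsewhere, so the minimum converted class count lands near 313.

:func:`make_shape_cloud` provides circle/sphere/torus fixtures for the
persistence engine.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .evaluation import LabelledDataset
from .persistence import PointCloud

__all__ = [
    "BlobSpec",
    "HandSpec",
    "STATIC_LETTERS",
    "make_gaussian_classes",
    "make_hand_like",
    "default_hand_spec",
    "build_balanced",
    "build_imbalanced",
    "make_shape_cloud",
]

#: The 24 static letters of the sign alphabet (J and Z need motion).
STATIC_LETTERS = tuple(c for c in string.ascii_uppercase if c not in "JZ")


# ---------------------------------------------------------------------------
# Gaussian blobs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlobSpec:
    """Isotropic Gaussian classes at mutually equidistant centers."""

    n_classes: int = 24
    sizes: Union[int, Sequence[int]] = 50
    n_features: int = 63
    separation: float = 20.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        sizes = self.class_sizes()
        if min(sizes) < 1:
            raise ValueError("class sizes must be >= 1")
        if self.separation <= 0 or self.sigma <= 0:
            raise ValueError("separation and sigma must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    def class_sizes(self) -> list[int]:
        if np.isscalar(self.sizes):
            return [int(self.sizes)] * self.n_classes
        sizes = [int(s) for s in self.sizes]
        if len(sizes) != self.n_classes:
            raise ValueError("per-class sizes must match n_classes")
        return sizes


def _equidistant_centers(k: int, m: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """k centers in R^m with pairwise distance exactly ``separation``.

    Random *orthonormal* directions scaled by separation/sqrt(2), so the
    between-class variance is spread over all coordinates rather than
    concentrated on k axes (axis-aligned centers would be flattened by
    per-feature standardization downstream).  Falls back to random unit
    directions (approximately equidistant) when m < k."""
    dirs = rng.normal(size=(k, m))
    if m >= k:
        dirs = np.linalg.qr(dirs.T)[0].T[:k]
    else:
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs * separation / np.sqrt(2.0)


def make_gaussian_classes(spec: BlobSpec) -> LabelledDataset:
    """Draw the blob dataset described by ``spec`` (reproducible per seed)."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.class_sizes()
    centers = _equidistant_centers(spec.n_classes, spec.n_features, spec.separation, rng)
    feats, labels = [], []
    for i, n in enumerate(sizes):
        feats.append(centers[i] + rng.normal(scale=spec.sigma, size=(n, spec.n_features)))
        labels.extend([i] * n)
    return LabelledDataset(np.vstack(feats), np.array(labels),
                           tuple(range(spec.n_classes)))


# ---------------------------------------------------------------------------
# hand-like landmark clouds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HandSpec:
    """Stylized 21-landmark hand poses with jitter and conversion failures.

    ``failure_rate`` is a scalar or per-class sequence of probabilities
    (each < 1) that a sample is "not converted" and excluded.  Templates
    are drawn deterministically from ``seed`` and are distinct across
    classes; ``template_overrides`` maps a class index to another class
    index whose template it shares (for constructing confusable pairs).
    """

    n_classes: int = 24
    class_size: int = 450
    jitter: float = 0.02
    translation: float = 0.05
    scale_range: float = 0.10
    failure_rate: Union[float, Sequence[float]] = 0.0
    seed: int = 0
    labels: Optional[Sequence] = None
    template_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_classes < 2 or self.class_size < 1:
            raise ValueError("need >= 2 classes of >= 1 sample")
        if self.jitter < 0 or self.translation < 0 or not 0 <= self.scale_range < 1:
            raise ValueError("invalid jitter/translation/scale_range")
        for r in self.failure_rates():
            if not 0.0 <= r < 1.0:
                raise ValueError("failure rates must lie in [0, 1)")

    def failure_rates(self) -> list[float]:
        if np.isscalar(self.failure_rate):
            return [float(self.failure_rate)] * self.n_classes
        rates = [float(r) for r in self.failure_rate]
        if len(rates) != self.n_classes:
            raise ValueError("per-class failure rates must match n_classes")
        return rates

    def class_labels(self) -> tuple:
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != self.n_classes:
                raise ValueError("labels must match n_classes")
            return labels
        if self.n_classes <= len(STATIC_LETTERS):
            return STATIC_LETTERS[: self.n_classes]
        return tuple(range(self.n_classes))


def default_hand_spec(seed: int = 0) -> HandSpec:
    """Study-shaped corpus: 24 letter classes x 450 samples; two classes
    fully converted, two with ~30% conversion failures (minimum converted
    count near 313), 5% elsewhere."""
    rates = [0.05] * 24
    rates[STATIC_LETTERS.index("F")] = 0.0
    rates[STATIC_LETTERS.index("U")] = 0.0
    rates[STATIC_LETTERS.index("M")] = 0.30
    rates[STATIC_LETTERS.index("Q")] = 0.30
    return HandSpec(n_classes=24, class_size=450, failure_rate=rates, seed=seed)


def _hand_template(rng: np.random.Generator) -> np.ndarray:
    """One stylized hand skeleton: wrist + 5 chains of 4 joints, (21, 3).

    Finger base angles fan across the palm; per-finger curl (drawn per
    class) bends successive segments and pushes joints out of plane, which
    is what distinguishes one pose from another."""
    wrist = np.zeros(3)
    pts = [wrist]
    base_angles = np.linspace(-0.7, 0.7, 5) + rng.normal(scale=0.05, size=5)
    curls = rng.uniform(0.0, 1.2, size=5)
    lengths = np.array([0.30, 0.26, 0.22, 0.18])
    for f in range(5):
        direction = np.array([np.sin(base_angles[f]), np.cos(base_angles[f]), 0.0])
        pos = wrist + direction * 0.35
        bend = 0.0
        for j in range(4):
            bend += curls[f] * (j + 1) / 4.0
            seg = np.array([
                np.sin(base_angles[f]) * np.cos(bend),
                np.cos(base_angles[f]) * np.cos(bend),
                -np.sin(bend) * 0.6,
            ])
            pos = pos + seg * lengths[j]
            pts.append(pos.copy())
    return np.array(pts)


def make_hand_like(spec: HandSpec):
    """Generate the hand-like dataset and its conversion report.

    Returns ``(LabelledDataset, report)`` where ``report`` maps class label
    to ``{"converted": c, "not_converted": nc}`` with ``c + nc`` equal to
    the requested class size.  Not-converted samples are excluded from the
    dataset.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.class_labels()
    rates = spec.failure_rates()
    templates = [_hand_template(rng) for _ in range(spec.n_classes)]
    for i, src in spec.template_overrides.items():
        templates[i] = templates[src]
    feats, row_labels = [], []
    report = {}
    for i, label in enumerate(labels):
        converted = 0
        for _ in range(spec.class_size):
            failed = rng.random() < rates[i]
            pts = templates[i] + rng.normal(scale=spec.jitter, size=(21, 3))
            scale = 1.0 + rng.uniform(-spec.scale_range, spec.scale_range)
            shift = rng.uniform(-spec.translation, spec.translation, size=3)
            pts = pts * scale + shift
            if failed:
                continue
            converted += 1
            feats.append(pts.ravel())
            row_labels.append(label)
        report[label] = {"converted": converted,
                         "not_converted": spec.class_size - converted}
    present = tuple(l for l in labels if report[l]["converted"] > 0)
    return (LabelledDataset(np.array(feats), np.array(row_labels), present), report)


# ---------------------------------------------------------------------------
# balanced / imbalanced builders
# ---------------------------------------------------------------------------


def build_balanced(data: LabelledDataset, seed: int = 0) -> LabelledDataset:
    """Uniform per-class subsample of size min over classes (seeded)."""
    counts = data.class_counts()
    target = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    for c in data.class_catalogue:
        idx = np.flatnonzero(data.labels == c)
        keep.append(rng.choice(idx, size=target, replace=False))
    return data.subset(np.sort(np.concatenate(keep)))


def build_imbalanced(data: LabelledDataset) -> LabelledDataset:
    """Identity pass-through: all converted samples with native counts."""
    return data


# ---------------------------------------------------------------------------
# geometric fixtures
# ---------------------------------------------------------------------------


def make_shape_cloud(shape: str, n: int, noise: float = 0.0, seed: int = 0) -> PointCloud:
    """Uniform sample on a unit circle, unit sphere or torus (R=2, r=0.5),
    plus isotropic Gaussian noise of the given standard deviation."""
    if n < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(seed)
    if shape == "circle":
        theta = rng.uniform(0, 2 * np.pi, size=n)
        pts = np.c_[np.cos(theta), np.sin(theta)]
    elif shape == "sphere":
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    elif shape == "torus":
        R, r = 2.0, 0.5
        theta = rng.uniform(0, 2 * np.pi, size=n)
        phi = np.empty(n)
        # area element ~ (R + r cos(phi)): rejection-sample the tube angle
        filled = 0
        while filled < n:
            cand = rng.uniform(0, 2 * np.pi, size=2 * (n - filled))
            accept = rng.uniform(0, 1, size=cand.size) < (R + r * np.cos(cand)) / (R + r)
            take = cand[accept][: n - filled]
            phi[filled:filled + take.size] = take
            filled += take.size
        pts = np.c_[(R + r * np.cos(phi)) * np.cos(theta),
                    (R + r * np.cos(phi)) * np.sin(theta),
                    r * np.sin(phi)]
    else:
        raise ValueError(f"unknown shape {shape!r}; expected circle, sphere or torus")
    if noise > 0:
        pts = pts + rng.normal(scale=noise, size=pts.shape)
    return PointCloud(pts)
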