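"""Dataset I/O and the optional image-to-landmark front end.

Feature tables travel as CSV with header ``id,label,<features...>`` —
canonically ``x0,y0,z0,...,x20,y20,z20`` for the 21 hand landmarks (x, y in
normalized image coordinates, z the relative depth with respect to the
camera), but any numeric feature columns are accepted.  Floats are printed
with 17 significant digits so a round trip is lossless.

Image extraction sits behind a single-function *port*: a backend callable
``image (H, W, 3) uint8 -> (21, 3) float array or None``.  The default
backend wraps the MediaPipe hand-landmark model when the ``landmarks``
extra is installed and raises :class:`ExtrasNotInstalledError` otherwise;
every other part of the package works without it (tests inject a synthetic
backend).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .evaluation import LabelledDataset

__all__ = [
    "LandmarkRecord",
    "ExtrasNotInstalledError",
    "read_feature_csv",
    "write_feature_csv",
    "read_point_cloud_csv",
    "extract_landmarks",
    "batch_extract",
    "write_conversion_report",
]

N_LANDMARKS = 21
N_FEATURES = 63

Backend = Callable[[np.ndarray], Optional[np.ndarray]]


class ExtrasNotInstalledError(RuntimeError):
    """The optional landmark backend (``phca[landmarks]``) is absent."""


@dataclass(frozen=True)
class LandmarkRecord:
    """One image's landmarks: 63 features ordered x0,y0,z0,...,x20,y20,z20."""

    image_id: str
    label: object
    features: Optional[np.ndarray]   # None when not converted

    @property
    def converted(self) -> bool:
        return self.features is not None

    def __post_init__(self) -> None:
        if self.features is not None:
            feats = np.asarray(self.features, dtype=float).ravel()
            if feats.shape[0] != N_FEATURES:
                raise ValueError(f"expected {N_FEATURES} features, got {feats.shape[0]}")
            if not np.isfinite(feats).all():
                raise ValueError("landmark coordinates must be finite")
            object.__setattr__(self, "features", feats)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def landmark_columns() -> list[str]:
    return [f"{axis}{i}" for i in range(N_LANDMARKS) for axis in ("x", "y", "z")]


def write_feature_csv(data: LabelledDataset, path: Union[str, Path],
                      ids: Optional[Sequence] = None,
                      landmark_headers: bool = False) -> None:
    """Write ``id,label,<features>`` with 17-significant-digit floats."""
    if landmark_headers and data.n_features != N_FEATURES:
        raise ValueError("landmark headers require exactly 63 features")
    cols = landmark_columns() if landmark_headers else [f"f{j}" for j in range(data.n_features)]
    frame = pd.DataFrame(data.features, columns=cols)
    frame.insert(0, "label", data.labels)
    frame.insert(0, "id", list(ids) if ids is not None else np.arange(data.n_rows))
    frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path: Union[str, Path]) -> LabelledDataset:
    """Read a feature table; first column is the id, second the label."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] < 3:
        raise ValueError("feature CSV needs id, label and at least one feature column")
    labels = frame.iloc[:, 1].to_numpy()
    feats = frame.iloc[:, 2:].to_numpy(dtype=float)
    _, idx = np.unique(labels, return_index=True)
    catalogue = tuple(labels[np.sort(idx)].tolist())
    return LabelledDataset(feats, labels, catalogue)


def read_point_cloud_csv(path: Union[str, Path]) -> np.ndarray:
    """Read a bare point-cloud CSV (numeric columns, optional header)."""
    frame = pd.read_csv(path)
    numeric = frame.select_dtypes("number")
    if numeric.empty:
        raise ValueError("point-cloud CSV has no numeric columns")
    return numeric.to_numpy(dtype=float)


def write_conversion_report(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(
        {str(k): v for k, v in report.items()}, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# extraction port
# ---------------------------------------------------------------------------


def _default_backend() -> Backend:
    try:
        import mediapipe  # noqa: F401
    except ImportError as exc:
        raise ExtrasNotInstalledError(
            "image-to-landmark extraction needs the optional backend; "
            "install with: pip install 'phca[landmarks]'"
        ) from exc
    import mediapipe as mp

    hands = mp.solutions.hands.Hands(static_image_mode=True, max_num_hands=1)

    def backend(image: np.ndarray) -> Optional[np.ndarray]:
        result = hands.process(image)
        if not result.multi_hand_landmarks:
            return None
        # single highest-confidence hand in static mode
        lm = result.multi_hand_landmarks[0].landmark
        return np.array([[p.x, p.y, p.z] for p in lm])

    return backend


def extract_landmarks(image: Union[str, Path, np.ndarray],
                      label=None,
                      backend: Optional[Backend] = None) -> LandmarkRecord:
    """Extract the 21 landmarks of the first detected hand from one image.

    ``image`` is a path (decoded with Pillow) or an ``(H, W, 3)`` array.
    Returns a converted :class:`LandmarkRecord`, or a not-converted marker
    when the backend finds no hand.
    """
    if backend is None:
        backend = _default_backend()
    if isinstance(image, (str, Path)):
        image_id = Path(image).name
        from PIL import Image

        with Image.open(image) as img:
            array = np.asarray(img.convert("RGB"))
    else:
        image_id = "<array>"
        array = np.asarray(image)
    landmarks = backend(array)
    if landmarks is None:
        return LandmarkRecord(image_id, label, None)
    return LandmarkRecord(image_id, label, np.asarray(landmarks, dtype=float).ravel())


def batch_extract(image_dir: Union[str, Path],
                  backend: Optional[Backend] = None):
    """Extract a dataset from a ``class/<files>`` directory layout.

    Classes and files are visited in lexicographic order.  Returns
    ``(LabelledDataset, report)`` with per-class converted / not-converted
    counts; classes with no converted image are reported but excluded.
    """
    root = Path(image_dir)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    if backend is None:
        backend = _default_backend()
    feats, labels, report = [], [], {}
    for cdir in class_dirs:
        converted = not_converted = 0
        for f in sorted(cdir.iterdir()):
            if not f.is_file():
                continue
            record = extract_landmarks(f, label=cdir.name, backend=backend)
            if record.converted:
                converted += 1
                feats.append(record.features)
                labels.append(cdir.name)
            else:
                not_converted += 1
        report[cdir.name] = {"converted": converted, "not_converted": not_converted}
    if not feats:
        raise ValueError(f"no image converted under {root}")
    catalogue = tuple(c.name for c in class_dirs if report[c.name]["converted"] > 0)
    return LabelledDataset(np.array(feats), np.array(labels), catalogue), report
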