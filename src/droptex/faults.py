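"""Fault detection: flag empty/failed wells before texture analysis.

The well interior (frame masked out) is z-scored and its gradient image
summarized by four moments plus a 50-bin absolute-gradient histogram; these
54 gradient statistics are combined with six droplet shape features (area,
well-relative centroid, eccentricity, major/minor axis lengths — zeros when
the drop could not be segmented) and fed to a two-class random forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .segmentation import DropletBoundary, WellRegistration, _shift_image

__all__ = [
    "FaultFeatureVector",
    "fault_features",
    "train_fault_classifier",
    "predict_fault",
]

N_GRAD_BINS = 50  # fixed unit-width bins centred at 0, 1, ..., 49
N_GRAD_FEATURES = N_GRAD_BINS + 4
N_FEATURES = N_GRAD_FEATURES + 6


@dataclass
class FaultFeatureVector:
    values: np.ndarray  # length 60

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features")

    @property
    def gradient_block(self) -> np.ndarray:
        return self.values[:N_GRAD_FEATURES]

    @property
    def shape_block(self) -> np.ndarray:
        return self.values[N_GRAD_FEATURES:]


def fault_features(
    image: np.ndarray,
    reg: WellRegistration,
    frame_mask: np.ndarray,
    boundary: DropletBoundary | None,
) -> FaultFeatureVector:
    """Gradient statistics of the frame-masked well plus droplet shape."""
    img = np.asarray(image, dtype=float)
    interior = ~_shift_image(frame_mask.astype(bool), reg.dy, reg.dx, fill=True)
    vals = img[interior]
    sd = vals.std()
    z = np.zeros_like(img)
    z[interior] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)

    gy, gx = np.gradient(z)
    grad = np.hypot(gy, gx)[interior]
    moments = [
        float(grad.mean()),
        float(grad.std()),
        float(stats.skew(grad)) if grad.std() > 0 else 0.0,
        float(stats.kurtosis(grad)) if grad.std() > 0 else 0.0,
    ]
    # unit-width bins centred 0..49; gradients beyond the range clip into
    # the last bin
    clipped = np.clip(grad, 0, N_GRAD_BINS - 0.51)
    hist, _ = np.histogram(
        clipped, bins=N_GRAD_BINS, range=(-0.5, N_GRAD_BINS - 0.5)
    )
    hist = hist / max(grad.size, 1)

    if boundary is not None and boundary.mask.any():
        # centroid relative to the registered well origin
        rows, cols = np.nonzero(interior)
        origin = (rows.min(), cols.min())
        shape = [
            boundary.area,
            boundary.centroid[1] - origin[1],
            boundary.centroid[0] - origin[0],
            boundary.eccentricity,
            boundary.major_axis,
            boundary.minor_axis,
        ]
    else:
        shape = [0.0] * 6
    return FaultFeatureVector(np.concatenate([moments, hist, shape]))


def _as_matrix(features) -> np.ndarray:
    rows = [
        f.values if isinstance(f, FaultFeatureVector) else np.asarray(f, float)
        for f in features
    ]
    return np.vstack(rows)


def train_fault_classifier(
    features, labels, n_trees: int = 200, seed: int = 0
) -> RandomForestClassifier:
    """Seeded random forest over fault feature vectors.

    ``labels`` hold 'good'/'faulty' (or any two classes).  The fitted model
    carries its out-of-bag accuracy in ``oob_score_``.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need both classes to train")
    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed
    )
    clf.fit(X, y)
    return clf


def predict_fault(model: RandomForestClassifier, features) -> pd.DataFrame:
    """Verdict and faulty-class probability per droplet."""
    X = _as_matrix(features)
    proba = model.predict_proba(X)
    verdict = model.predict(X)
    faulty_col = list(model.classes_).index("faulty") if "faulty" in model.classes_ else 1
    return pd.DataFrame(
        {"verdict": verdict, "p_faulty": proba[:, faulty_col]}
    )
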