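"""Axon / autofluorescence pixel segmentation.

Two approaches to separating GFP-like axon signal from lipofuscin-like puncta
that fluoresce in both channels:

* channel subtraction — subtract the normalised red (autofluorescence)
  channel from the green channel, exploiting the puncta's broad emission;
* a trainable pixel classifier — a fixed multi-scale feature bank over both
  channels feeding a random forest, used for all quantitative outputs.

Segmentations are scored with the precision-recall F measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage
from skimage import filters
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "SegScore",
    "PixelClassifier",
    "subtract_channels",
    "extract_features",
    "feature_names",
    "train_classifier",
    "classify",
    "evaluate_fscore",
    "sample_training_pixels",
]

SERIALIZATION_VERSION = 1

#: smoothing scales (pixels) of the feature bank
FEATURE_SCALES = (1.0, 2.0, 4.0)


@dataclass(frozen=True)
class SegScore:
    """Precision, recall and their harmonic mean for one binary segmentation."""

    precision: float
    recall: float
    f_score: float

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall, "f_score": self.f_score}


# ---------------------------------------------------------------------------
# channel subtraction
# ---------------------------------------------------------------------------

def _puncta_normalization_scale(green: np.ndarray, red: np.ndarray) -> float:
    """Red-channel scale factor from candidate puncta.

    Candidate puncta are the brightest red pixels (top 0.5%); the scale is the
    ratio of 99th-percentile green to 99th-percentile red intensity over them,
    which is robust to global gain differences between channels.
    """
    cutoff = np.quantile(red, 0.995)
    cand = red >= cutoff
    if not cand.any():
        return 1.0
    g99 = np.quantile(green[cand], 0.99)
    r99 = np.quantile(red[cand], 0.99)
    if r99 <= 0:
        return 1.0
    return float(g99 / r99)


def subtract_channels(
    green: np.ndarray,
    red: np.ndarray,
    norm_mode: str = "puncta-quantile",
    scale: float | None = None,
) -> np.ndarray:
    """Autofluorescence subtraction: ``clip(green - s * red, 0)``.

    ``norm_mode`` selects the normalisation scalar s: ``"unit"`` uses 1,
    ``"puncta-quantile"`` matches the channels' 99th-percentile intensities
    over the brightest red pixels.  An explicit ``scale`` overrides both.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red must have the same shape")
    if scale is not None:
        s = float(scale)
    elif norm_mode == "unit":
        s = 1.0
    elif norm_mode == "puncta-quantile":
        s = _puncta_normalization_scale(green, red)
    else:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    return np.clip(green - s * red, 0.0, None)


# ---------------------------------------------------------------------------
# feature bank
# ---------------------------------------------------------------------------

def feature_names() -> list[str]:
    names = ["green_raw", "red_raw", "green_red_ratio"]
    for s in FEATURE_SCALES:
        names.append(f"green_gauss_{s:g}")
    for s in FEATURE_SCALES:
        names.append(f"red_gauss_{s:g}")
    for s in FEATURE_SCALES[:2]:
        names.append(f"green_gradmag_{s:g}")
    names.append("green_tubularity_1")
    return names


def extract_features(green: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Fixed-order per-pixel feature stack, shape (H, W, n_features).

    Raw intensities of both channels, multi-scale Gaussian-smoothed
    intensities, green gradient magnitudes, a bright-ridge (tubularity)
    response on the green channel, and the green/red ratio.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red must have the same shape")
    feats = [green, red, green / (red + 1.0)]
    for s in FEATURE_SCALES:
        feats.append(ndimage.gaussian_filter(green, s))
    for s in FEATURE_SCALES:
        feats.append(ndimage.gaussian_filter(red, s))
    for s in FEATURE_SCALES[:2]:
        feats.append(ndimage.gaussian_gradient_magnitude(green, s))
    feats.append(filters.sato(green, sigmas=[1.0], black_ridges=False))
    return np.stack(feats, axis=-1)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class PixelClassifier:
    """Trainable two-class (axon vs background) per-pixel classifier."""

    feature_bank: tuple[str, ...]
    model: RandomForestClassifier | None = None

    @property
    def trained(self) -> bool:
        return self.model is not None and hasattr(self.model, "estimators_")

    def save(self, path) -> None:
        joblib.dump(
            {
                "version": SERIALIZATION_VERSION,
                "feature_bank": self.feature_bank,
                "model": self.model,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        payload = joblib.load(path)
        if payload.get("version") != SERIALIZATION_VERSION:
            raise ValueError("unsupported classifier file version")
        return cls(feature_bank=tuple(payload["feature_bank"]), model=payload["model"])


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 40,
    max_depth: int | None = 16,
) -> PixelClassifier:
    """Fit the forest on labeled pixels; deterministic under ``seed``."""
    features = np.asarray(features)
    labels = np.asarray(labels).astype(bool)
    if features.ndim != 2:
        raise ValueError("features must be (n_pixels, n_features)")
    if labels.shape[0] != features.shape[0]:
        raise ValueError("labels length must match features")
    if labels.all() or not labels.any():
        raise ValueError("training labels must contain both classes")
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(features, labels)
    return PixelClassifier(feature_bank=tuple(feature_names()), model=model)


def classify(clf: PixelClassifier, green: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Binary axon mask (True = axon) for one two-channel section."""
    if not clf.trained:
        raise ValueError("classifier has not been trained")
    feats = extract_features(green, red)
    flat = feats.reshape(-1, feats.shape[-1])
    pred = clf.model.predict(flat)
    return pred.reshape(green.shape).astype(bool)


def sample_training_pixels(
    green: np.ndarray,
    red: np.ndarray,
    truth_mask: np.ndarray,
    n_per_class: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a balanced labeled pixel sample from one section and its truth."""
    feats = extract_features(green, red)
    flat = feats.reshape(-1, feats.shape[-1])
    truth = np.asarray(truth_mask).ravel().astype(bool)
    pos = np.flatnonzero(truth)
    neg = np.flatnonzero(~truth)
    n_pos = min(n_per_class, pos.size)
    n_neg = min(n_per_class, neg.size)
    take = np.concatenate(
        [
            rng.choice(pos, size=n_pos, replace=False) if n_pos else np.empty(0, int),
            rng.choice(neg, size=n_neg, replace=False) if n_neg else np.empty(0, int),
        ]
    )
    return flat[take], truth[take]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def evaluate_fscore(pred: np.ndarray, truth: np.ndarray) -> SegScore:
    """Precision-recall F measure of a binary segmentation.

    Conventions for empty denominators: if both prediction and truth are
    empty the segmentation is perfect, (1, 1, 1); a prediction with no
    positives against a non-empty truth has precision 0; a non-empty
    prediction against an empty truth has recall 0.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same shape")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    if tp + fp + fn == 0:
        return SegScore(1.0, 1.0, 1.0)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return SegScore(precision, recall, f)
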