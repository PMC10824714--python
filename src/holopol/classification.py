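"""Material classification from polarimetric particle features.

The discriminative signal for material identity is birefringence, which
appears directly in two low-dimensional per-particle features: the SSD
(stack standard deviation over the four analyzer channels) and the
DoLP, both proportional to |sin delta| of the material's retardance
delta.  A nearest-centroid classifier on standardized features is
therefore sufficient, fully deterministic, and keeps the feature claim
falsifiable; a plug-in interface is unnecessary complexity at this
dimensionality, but the model is a plain serializable object so
alternatives can be swapped in by callers.

Evaluation follows a stratified, seeded 8:1:1
training/validation/test split; the validation slice is reserved for
tuning segmentation thresholds and is not consumed by the centroid
model itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError, InsufficientDataError

__all__ = [
    "FEATURE_NAMES",
    "SplitSpec",
    "CentroidModel",
    "extract_features",
    "split_dataset",
    "train_centroids",
    "predict",
    "evaluate",
]

#: Order of the per-particle feature vector components.
FEATURE_NAMES = ("ssd_mean", "ssd_p90", "dolp_mean", "transmittance_mean")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test ratios (default 8:1:1) and shuffle seed."""

    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.ratios) or sum(self.ratios) <= 0:
            raise ValueError("ratios must be non-negative with positive sum")


def extract_features(
    mask: np.ndarray,
    ssd,
    dolp,
    transmittance: np.ndarray | None = None,
    erode_px: int = 0,
) -> np.ndarray:
    """Feature vector (mean SSD, p90 SSD, mean DoLP, mean transmittance)
    over the valid pixels of a particle mask.

    ``erode_px`` optionally shrinks the mask before sampling so that
    edge pixels — where diffraction mixes particle and background
    light — do not dilute the interior statistics; if erosion empties
    the mask the original is used.
    """
    mask = np.asarray(mask, dtype=bool)
    if erode_px > 0:
        from skimage.morphology import erosion, disk

        shrunk = erosion(mask, disk(erode_px))
        if shrunk.any():
            mask = shrunk
    sel_ssd = mask & ssd.valid
    sel_dolp = mask & dolp.valid
    if not sel_ssd.any() or not sel_dolp.any():
        raise EmptyRegionError("mask does not overlap the valid feature maps")
    svals = ssd.values[sel_ssd]
    trans = (
        float(np.asarray(transmittance, dtype=float)[mask].mean())
        if transmittance is not None
        else 1.0
    )
    return np.array([
        float(svals.mean()),
        float(np.percentile(svals, 90)),
        float(dolp.values[sel_dolp].mean()),
        trans,
    ])


def split_dataset(labels, spec: SplitSpec = SplitSpec()):
    """Stratified, seeded index split into (train, val, test).

    Within each class, indices are shuffled and allocated by largest
    remainder, so split sizes match the exact ratios to within one
    record per class; the three sets partition the input.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InsufficientDataError("no records to split")
    rng = np.random.default_rng(spec.seed)
    fractions = np.asarray(spec.ratios, dtype=float) / sum(spec.ratios)

    def largest_remainder(n):
        quota = fractions * n
        base = np.floor(quota).astype(int)
        rem = quota - base
        for _ in range(n - base.sum()):
            k = int(np.argmax(rem))
            base[k] += 1
            rem[k] = -1
        return base

    parts: list[list[int]] = [[], [], []]
    per_class: dict = {}
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        stops = np.cumsum(largest_remainder(len(idx)))
        chunks = (idx[: stops[0]], idx[stops[0] : stops[1]], idx[stops[1] : stops[2]])
        per_class[cls] = [list(c) for c in chunks]
        for p, c in zip(parts, chunks):
            p.extend(c)

    # Per-class allocation can leave the global sizes a few records off the
    # exact ratios; rebalance by moving single records between sets,
    # preferring the class currently most represented in the donor set so
    # per-class deviations stay within one record.
    targets = largest_remainder(len(labels))
    for src in range(3):
        for dst in range(3):
            while len(parts[src]) > targets[src] and len(parts[dst]) < targets[dst]:
                donor_cls = max(per_class, key=lambda c: len(per_class[c][src]))
                moved = per_class[donor_cls][src].pop()
                per_class[donor_cls][dst].append(moved)
                parts[src].remove(moved)
                parts[dst].append(moved)
    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)


@dataclass
class CentroidModel:
    """Nearest-centroid classifier in standardized feature space."""

    class_order: list[str]
    feature_names: list[str]
    mean: np.ndarray  # training mean per retained feature
    sd: np.ndarray  # training sd per retained feature (all > 0)
    kept: np.ndarray  # boolean mask over the raw feature axes
    centroids: np.ndarray  # (n_classes, n_kept)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X[:, self.kept] - self.mean) / self.sd

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_order": self.class_order,
                "feature_names": self.feature_names,
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
                "kept": self.kept.astype(int).tolist(),
                "centroids": self.centroids.tolist(),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CentroidModel":
        d = json.loads(text)
        return cls(
            class_order=list(d["class_order"]),
            feature_names=list(d["feature_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            kept=np.asarray(d["kept"], dtype=bool),
            centroids=np.asarray(d["centroids"], dtype=float),
        )


def train_centroids(features: np.ndarray, labels, feature_names=FEATURE_NAMES) -> CentroidModel:
    """Standardize by training statistics and average per class.

    Zero-variance features are dropped (they carry no class signal and
    would divide by zero).  Classes are ordered by sorted label.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if len(X) != len(y) or len(X) == 0:
        raise InsufficientDataError("features and labels must be non-empty and aligned")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = sd > 0
    if not kept.any():
        raise InsufficientDataError("all features have zero variance")
    Xs = (X[:, kept] - mean[kept]) / sd[kept]
    classes = [str(c) for c in np.unique(y)]
    centroids = np.stack([Xs[y == c].mean(axis=0) for c in np.unique(y)])
    return CentroidModel(
        class_order=classes,
        feature_names=list(feature_names),
        mean=mean[kept],
        sd=sd[kept],
        kept=kept,
        centroids=centroids,
    )


def predict(model: CentroidModel, features: np.ndarray):
    """Nearest centroid in standardized Euclidean distance.

    Returns ``(labels, margins)`` where the margin is the distance gap
    between the runner-up and the chosen centroid (0 for a single
    class).  Exact ties resolve to the first class in model order.
    """
    Xs = model.standardize(features)
    dists = np.linalg.norm(Xs[:, None, :] - model.centroids[None, :, :], axis=2)
    best = np.argmin(dists, axis=1)  # argmin takes the first index on ties
    labels = [model.class_order[i] for i in best]
    if dists.shape[1] > 1:
        part = np.partition(dists, 1, axis=1)
        margins = part[:, 1] - part[:, 0]
    else:
        margins = np.zeros(len(labels))
    return labels, margins


def evaluate(model: CentroidModel, features: np.ndarray, labels):
    """Accuracy and per-class confusion matrix on a labelled set.

    Returns ``(accuracy, confusion)``; the confusion matrix is a
    DataFrame with true classes as rows and predicted as columns, so
    row sums equal the per-class test counts.
    """
    import pandas as pd

    y = np.asarray([str(v) for v in labels])
    pred, _ = predict(model, features)
    acc = float(np.mean(np.asarray(pred) == y))
    classes = model.class_order
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, pred):
        if t in conf.index:
            conf.loc[t, p] += 1
    return acc, conf
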