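"""Augmentation, stratified cross-validation, and per-plane model training.

The classifier consumed by the ensembles is a *plane model*: a function from
a normalized representative image (one (method, plane) combination) to a
class-probability vector, together with provenance metadata. Training data
is expanded eight-fold by the rotation/flip augmentation set
{identity, R, H, V, R∘H, R∘V, H∘V, R∘H∘V}, where R is a rotation by one
angle drawn uniformly from ±20° per source image and H/V are horizontal and
vertical flips — the only composition consistent with an 8× expansion.

Cross-validation partitions samples into k stratified folds; augmentation is
applied to training folds only, so no transformed copy of a held-out image
ever leaks into training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from ._nn import SmallCNN
from .ensemble import ClassProbabilities
from .preprocess import ConversionMethod, Plane, WindowParams, project, apply_window, resize

__all__ = [
    "AugmentationPolicy",
    "FoldAssignment",
    "TrainConfig",
    "PlaneModel",
    "augment",
    "stratified_kfold",
    "train_plane_model",
    "cross_validate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Rotation/flip augmentation set applied to training images."""

    rotation_range: tuple[float, float] = (-20.0, 20.0)
    use_hflip: bool = True
    use_vflip: bool = True

    @property
    def outputs_per_input(self) -> int:
        n_ops = int(self.rotation_range is not None) + self.use_hflip + self.use_vflip
        return 2 ** n_ops


@dataclass(frozen=True)
class FoldAssignment:
    """Test-fold index per sample from a stratified k-fold split."""

    fold_of: tuple[int, ...]
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) != fold)


@dataclass
class TrainConfig:
    """Configuration of one plane-model training run.

    ``input_size`` is the square side length the network actually consumes;
    representative images are resized down from the preprocessing output.
    64 px retains the geometry that separates the phantom classes while
    keeping CPU training in the seconds-to-minutes range.
    """

    n_classes: int = 5
    backbone: str = "reference_cnn"
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    input_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32)
    early_stop: bool = True

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 5):
            raise ValueError("n_classes must be 2 or 5")
        if self.backbone not in ("reference_cnn", "pretrained_backbone"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


def _rotate(image: np.ndarray, angle: float) -> np.ndarray:
    out = ndimage.rotate(
        image, angle, reshape=False, order=1, mode="constant", cval=0.0
    )
    return np.clip(out, 0.0, 1.0)


def augment(
    image: np.ndarray,
    policy: AugmentationPolicy = AugmentationPolicy(),
    seed: int = 0,
) -> list[np.ndarray]:
    """Return the augmentation set of *image* (original first).

    One rotation angle is drawn per input image (seeded); flips and the
    rotation are composed over all subsets of the enabled operations, giving
    ``policy.outputs_per_input`` images (8 under defaults). Rotation fills
    exposed corners with 0 — air after windowing. A degenerate rotation
    range (lo == hi == 0 or None) reduces R to the identity.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("augment expects a 2D image")
    rng = np.random.default_rng(seed)
    ops: list[list[str]] = [[]]
    enabled = []
    if policy.rotation_range is not None:
        enabled.append("R")
    if policy.use_hflip:
        enabled.append("H")
    if policy.use_vflip:
        enabled.append("V")
    # subsets in canonical order: (), R, H, V, RH, RV, HV, RHV
    from itertools import combinations

    for r in range(1, len(enabled) + 1):
        ops.extend(list(c) for c in combinations(enabled, r))

    if policy.rotation_range is not None:
        lo, hi = policy.rotation_range
        angle = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    else:
        angle = 0.0

    out = []
    for combo in ops:
        img = image
        if "H" in combo:
            img = np.fliplr(img)
        if "V" in combo:
            img = np.flipud(img)
        if "R" in combo and angle != 0.0:
            img = _rotate(img, angle)
        out.append(np.ascontiguousarray(img))
    return out


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment: per-class counts across folds differ ≤ 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() >= k:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_of = np.empty(len(labels), dtype=int)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            fold_of[test_idx] = fold
    else:
        warnings.warn(
            f"some class has fewer than k={k} members; using round-robin stratification",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        fold_of = np.empty(len(labels), dtype=int)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % k
    return FoldAssignment(tuple(int(f) for f in fold_of), k, seed)


class PlaneModel:
    """A trained per-plane classifier honouring the probability contract."""

    def __init__(
        self,
        net: SmallCNN,
        classes: tuple[str, ...],
        method: ConversionMethod | None = None,
        plane: Plane | None = None,
        config: TrainConfig | None = None,
    ) -> None:
        self.net = net
        self.classes = tuple(classes)
        self.method = ConversionMethod(method) if method is not None else None
        self.plane = Plane(plane) if plane is not None else None
        self.config = config

    def predict_proba(self, model_input: np.ndarray) -> ClassProbabilities:
        """Probability vector for one 299×299×3 model input (or 2D image)."""
        x = np.asarray(model_input, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, :, 0]
        x = resize(x, self.net.input_size)
        probs = self.net.predict_proba(x)
        return ClassProbabilities(np.asarray(probs, dtype=np.float64), self.classes)

    def predict_proba_batch(self, images: np.ndarray) -> np.ndarray:
        """Raw probability matrix for a batch of 2D images at network size."""
        return self.net.predict_proba(np.asarray(images, dtype=np.float64))


def _prepare_batch(inputs, size: int) -> np.ndarray:
    """Stack model inputs / 2D images into an (N, size, size) batch."""
    batch = np.empty((len(inputs), size, size), dtype=np.float64)
    for i, img in enumerate(inputs):
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[:, :, 0]
        batch[i] = resize(arr, size)
    return batch


def train_plane_model(
    inputs,
    labels,
    config: TrainConfig,
    method: ConversionMethod | None = None,
    plane: Plane | None = None,
    log=None,
) -> PlaneModel:
    """Train the reference classifier on a list of model inputs.

    *inputs* may be 299×299×3 tensors or plain 2D windowed images; they are
    resized to ``config.input_size`` internally. Class order is the sorted
    set of observed label strings.
    """
    if config.backbone == "pretrained_backbone":
        raise NotImplementedError(
            "no pretrained backbone is bundled; use backbone='reference_cnn'"
        )
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if len(classes) != config.n_classes:
        raise ValueError(
            f"config.n_classes={config.n_classes} but {len(classes)} classes present"
        )
    label_idx = np.array([classes.index(l) for l in labels], dtype=int)
    x = _prepare_batch(inputs, config.input_size)
    net = SmallCNN(config.input_size, config.n_classes, config.channels, config.seed)
    net.fit(
        x, label_idx,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        early_stop=config.early_stop,
        log=log,
    )
    return PlaneModel(net, classes, method, plane, config)


def cross_validate(
    volumes,
    labels,
    method: ConversionMethod,
    plane: Plane,
    config: TrainConfig,
    k: int = 5,
    policy: AugmentationPolicy = AugmentationPolicy(),
    window: WindowParams = WindowParams(),
):
    """k-fold cross-validation of one (method, plane) classifier.

    Projects every volume once, then for each fold augments the training
    images only, trains a fresh model, and evaluates on the raw held-out
    images. Returns a list of per-fold
    :class:`~ctqc.evaluation.MetricsReport`.
    """
    from .evaluation import confusion_matrix, metrics

    images = [
        apply_window(project(v, method, plane), window).pixels for v in volumes
    ]
    labels = list(labels)
    assignment = stratified_kfold(labels, k=k, seed=config.seed)
    classes = tuple(sorted(set(labels)))
    reports = []
    for fold in range(k):
        train_idx = assignment.train_indices(fold)
        test_idx = assignment.test_indices(fold)
        train_imgs, train_labels = [], []
        for j, i in enumerate(train_idx):
            for aug in augment(images[i], policy, seed=config.seed * 100003 + int(i)):
                train_imgs.append(aug)
                train_labels.append(labels[i])
        fold_config = TrainConfig(**{**asdict(config), "seed": config.seed + fold})
        model = train_plane_model(train_imgs, train_labels, fold_config, method, plane)
        test_batch = _prepare_batch([images[i] for i in test_idx], config.input_size)
        probs = model.predict_proba_batch(test_batch)
        predicted = [model.classes[i] for i in probs.argmax(axis=1)]
        truth = [labels[i] for i in test_idx]
        reports.append(metrics(confusion_matrix(truth, predicted, classes)))
    return reports


def save_model(model: PlaneModel, path: str | Path) -> Path:
    """Save weights (npz) plus a JSON metadata sidecar next to them."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.net.state_dict())
    sidecar = {
        "format_version": 1,
        "classes": list(model.classes),
        "method": model.method.value if model.method else None,
        "plane": model.plane.value if model.plane else None,
        "input_size": model.net.input_size,
        "channels": list(model.net.channels),
        "n_classes": model.net.n_classes,
        "seed": model.net.seed,
        "config": asdict(model.config) if model.config else None,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> PlaneModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    net = SmallCNN(
        meta["input_size"], meta["n_classes"], tuple(meta["channels"]), meta["seed"]
    )
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    config = TrainConfig(**{
        **meta["config"], "channels": tuple(meta["config"]["channels"])
    }) if meta.get("config") else None
    return PlaneModel(net, tuple(meta["classes"]), meta["method"], meta["plane"], config)
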