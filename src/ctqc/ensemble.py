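"""Soft-voting ensembles and the end-to-end two-module QC pipeline.

Each module combines m = 3 per-plane classifiers by *soft voting*: the final
class is

    y = argmax_i  Σ_{j=1..m} p_ij

where p_ij is member j's predicted probability of class i. Sums are kept
unnormalized (range [0, m]); ties resolve to the lowest class index and are
flagged. Soft voting is not majority voting — a member with a confident
probability can outvote two lukewarm opponents — and the implementation is
checked against an exhaustive-sum oracle in the test suite.

The body-part module votes over the three MIP-plane classifiers (5 classes);
the contrast module votes over the three mid-plane classifiers (2 classes),
either one global triple or one triple per body part routed by the predicted
body part.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .preprocess import ConversionMethod, Plane, WindowParams, convert_series
from .volume_io import CTVolume

__all__ = [
    "ClassProbabilities",
    "EnsembleConfig",
    "QCResult",
    "CONTRAST_CLASSES",
    "soft_vote",
    "build_body_part_module",
    "build_contrast_module",
    "run_imageqc",
]

# canonical plane order for ensemble members
PLANE_ORDER = (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)
CONTRAST_CLASSES = ("contrast", "non_contrast")


@dataclass
class ClassProbabilities:
    """One classifier's probability vector over a labelled class set."""

    values: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.classes = tuple(self.classes)
        if self.values.ndim != 1 or len(self.values) != len(self.classes):
            raise ValueError("probability vector and class set lengths differ")
        if np.any(self.values < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.values.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1 within 1e-6")


def soft_vote(prob_vectors) -> tuple[int, np.ndarray]:
    """Sum member probability vectors per class and take the argmax.

    Returns ``(winning_class_index, summed_scores)`` with the scores left
    unnormalized. Ties break to the lowest class index (numpy argmax
    semantics). All members must share one class set.
    """
    vectors = list(prob_vectors)
    if not vectors:
        raise ValueError("soft_vote requires at least one probability vector")
    classes = vectors[0].classes
    for v in vectors[1:]:
        if v.classes != classes:
            raise ValueError(f"mismatched class sets: {v.classes} vs {classes}")
    summed = np.sum([v.values for v in vectors], axis=0)
    return int(np.argmax(summed)), summed


@dataclass
class EnsembleConfig:
    """m per-plane members sharing one class set, combined by soft voting."""

    members: list  # [(ConversionMethod, Plane, PlaneModel), ...]
    classes: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def predict(self, member_inputs) -> tuple[int, np.ndarray, list[ClassProbabilities]]:
        """Vote over per-member model inputs (same order as ``members``)."""
        probs = [
            model.predict_proba(x)
            for (_, _, model), x in zip(self.members, member_inputs, strict=True)
        ]
        winner, summed = soft_vote(probs)
        return winner, summed, probs


def _build_module(models, expected_method: ConversionMethod, n_classes: int) -> EnsembleConfig:
    if isinstance(models, Mapping):
        lookup = {(ConversionMethod(m), Plane(p)): mod for (m, p), mod in models.items()}
    else:
        lookup = {(mod.method, mod.plane): mod for mod in models}
    members = []
    classes = None
    for plane in PLANE_ORDER:
        key = (expected_method, plane)
        if key not in lookup:
            raise ValueError(f"missing member for ({expected_method.value}, {plane.value})")
        model = lookup[key]
        if len(model.classes) != n_classes:
            raise ValueError(
                f"member ({expected_method.value}, {plane.value}) has "
                f"{len(model.classes)} classes, expected {n_classes}"
            )
        if classes is None:
            classes = model.classes
        elif model.classes != classes:
            raise ValueError("ensemble members disagree on the class set")
        members.append((expected_method, plane, model))
    return EnsembleConfig(members, classes)


def build_body_part_module(models) -> EnsembleConfig:
    """Three 5-class MIP-plane models → the body-part soft-voting module.

    *models* is either a mapping ``{(method, plane): PlaneModel}`` or an
    iterable of models carrying their own (method, plane) metadata. Members
    are ordered axial, sagittal, coronal.
    """
    return _build_module(models, ConversionMethod.MIP, 5)


def build_contrast_module(models, per_body_part: bool = False):
    """Three 2-class mid-plane models → the contrast soft-voting module.

    With ``per_body_part=True``, *models* maps each body-part label to its
    own model triple and the result is a dict of modules keyed by body part;
    at inference the module is selected by the predicted body part.
    """
    if per_body_part:
        if not isinstance(models, Mapping):
            raise ValueError("per_body_part=True requires {body_part: models} mapping")
        return {
            part: _build_module(sub, ConversionMethod.MID, 2)
            for part, sub in models.items()
        }
    return _build_module(models, ConversionMethod.MID, 2)


@dataclass
class QCResult:
    """Final QC decision for one series, with full voting audit trail."""

    series_id: str
    body_part: str
    body_scores: dict[str, float]
    body_member_probs: list[dict[str, float]]
    body_tie: bool
    contrast: str
    contrast_scores: dict[str, float]
    contrast_member_probs: list[dict[str, float]]
    contrast_tie: bool
    thumbnail_mid: str | None = None
    thumbnail_mip: str | None = None

    def to_dict(self) -> dict:
        return {
            "series_id": self.series_id,
            "body_part": self.body_part,
            "body_scores": self.body_scores,
            "body_member_probs": self.body_member_probs,
            "body_tie": self.body_tie,
            "contrast": self.contrast,
            "contrast_scores": self.contrast_scores,
            "contrast_member_probs": self.contrast_member_probs,
            "contrast_tie": self.contrast_tie,
            "thumbnail_mid": self.thumbnail_mid,
            "thumbnail_mip": self.thumbnail_mip,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return path


def _is_tie(summed: np.ndarray) -> bool:
    best = summed.max()
    return int(np.sum(np.isclose(summed, best, rtol=0, atol=1e-12))) > 1


def run_imageqc(
    volume: CTVolume,
    body_module: EnsembleConfig,
    contrast_modules,
    w: WindowParams = WindowParams(),
    thumbnail_dir: str | Path | None = None,
) -> QCResult:
    """Classify one CT volume end to end.

    Computes the three MIP projections and votes on body part; then the
    three mid-plane projections and votes on contrast, routing to a
    per-body-part contrast module when *contrast_modules* is a mapping
    (falling back to its ``"global"`` entry if the predicted part has no
    triple). Writes mid-coronal and MIP-coronal thumbnails when
    *thumbnail_dir* is given. The result carries every member probability
    vector for auditability.
    """
    thumbs: dict[str, str] = {}

    def member_input(method: ConversionMethod, plane: Plane):
        want_png = thumbnail_dir is not None and plane is Plane.CORONAL
        png_path, model_in = convert_series(
            volume, method, plane, w, out_dir=thumbnail_dir if want_png else None
        )
        if png_path is not None:
            thumbs[method.value] = str(png_path)
        return model_in

    body_inputs = [member_input(m, p) for (m, p, _) in body_module.members]
    body_idx, body_scores, body_probs = body_module.predict(body_inputs)
    body_label = body_module.classes[body_idx]

    if isinstance(contrast_modules, Mapping):
        module = contrast_modules.get(body_label) or contrast_modules.get("global")
        if module is None:
            raise ValueError(
                f"no contrast module for body part {body_label!r} and no global fallback"
            )
    else:
        module = contrast_modules
    contrast_inputs = [member_input(m, p) for (m, p, _) in module.members]
    contrast_idx, contrast_scores, contrast_probs = module.predict(contrast_inputs)

    return QCResult(
        series_id=volume.series_id,
        body_part=body_label,
        body_scores={c: float(s) for c, s in zip(body_module.classes, body_scores)},
        body_member_probs=[
            {c: float(p) for c, p in zip(v.classes, v.values)} for v in body_probs
        ],
        body_tie=_is_tie(body_scores),
        contrast=module.classes[contrast_idx],
        contrast_scores={c: float(s) for c, s in zip(module.classes, contrast_scores)},
        contrast_member_probs=[
            {c: float(p) for c, p in zip(v.classes, v.values)} for v in contrast_probs
        ],
        contrast_tie=_is_tie(contrast_scores),
        thumbnail_mid=thumbs.get("MID"),
        thumbnail_mip=thumbs.get("MIP"),
    )
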