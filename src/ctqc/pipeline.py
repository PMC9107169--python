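"""High-level orchestration: train the two-module system and classify series.

Glues the lower layers together for the CLI and for scripted experiments:
train the three MIP-plane body-part classifiers and the mid-plane contrast
classifiers (one global triple, or one per body part), assemble the
soft-voting modules, and run batch classification.
"""

from __future__ import annotations

import numpy as np

from .ensemble import (
    CONTRAST_CLASSES,
    EnsembleConfig,
    QCResult,
    build_body_part_module,
    build_contrast_module,
    run_imageqc,
)
from .preprocess import ConversionMethod, Plane, WindowParams, apply_window, project
from .training import AugmentationPolicy, PlaneModel, TrainConfig, augment, train_plane_model

__all__ = [
    "BODY_PLANES",
    "contrast_label",
    "train_plane_models",
    "train_two_module_system",
    "classify_volumes",
]

BODY_PLANES = (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)


def contrast_label(flag: bool) -> str:
    return CONTRAST_CLASSES[0] if flag else CONTRAST_CLASSES[1]


def _augmented_training_set(images, labels, policy, seed):
    out_imgs, out_labels = [], []
    for i, (img, label) in enumerate(zip(images, labels)):
        for aug in augment(img, policy, seed=(seed * 100003 + i) % (2**31)):
            out_imgs.append(aug)
            out_labels.append(label)
    return out_imgs, out_labels


def train_plane_models(
    volumes,
    labels,
    method: ConversionMethod,
    config: TrainConfig,
    policy: AugmentationPolicy = AugmentationPolicy(),
    window: WindowParams = WindowParams(),
    planes=BODY_PLANES,
    log=None,
) -> dict:
    """Train one classifier per plane for a fixed conversion method.

    Returns ``{(method, plane): PlaneModel}``. Projections are windowed at
    the native grid, augmented, and resized inside the trainer.
    """
    models = {}
    for p, plane in enumerate(planes):
        images = [apply_window(project(v, method, plane), window).pixels for v in volumes]
        train_imgs, train_labels = _augmented_training_set(
            images, labels, policy, seed=config.seed + 7919 * p
        )
        plane_config = TrainConfig(**{
            **config.__dict__, "seed": (config.seed + 101 * p) % (2**31)
        })
        if log is not None:
            log(f"training {method.value} {plane.value} "
                f"({len(train_imgs)} images, {plane_config.n_classes} classes)")
        models[(method, plane)] = train_plane_model(
            train_imgs, train_labels, plane_config, method, plane, log=log
        )
    return models


def train_two_module_system(
    volumes,
    body_labels,
    contrast_flags,
    config: TrainConfig | None = None,
    per_body_part: bool = False,
    policy: AugmentationPolicy = AugmentationPolicy(),
    window: WindowParams = WindowParams(),
    log=None,
):
    """Train body-part + contrast modules on labelled volumes.

    Returns ``(body_module, contrast_modules)`` where *contrast_modules* is
    a single :class:`EnsembleConfig` or, with ``per_body_part=True``, a dict
    keyed by body part (with a ``"global"`` fallback triple).
    """
    config = config or TrainConfig()
    body_config = TrainConfig(**{**config.__dict__, "n_classes": 5})
    con_config = TrainConfig(**{**config.__dict__, "n_classes": 2, "seed": config.seed + 50021})

    body_models = train_plane_models(
        volumes, list(body_labels), ConversionMethod.MIP, body_config,
        policy, window, log=log,
    )
    body_module = build_body_part_module(body_models)

    con_labels = [contrast_label(f) for f in contrast_flags]
    if per_body_part:
        modules = {}
        global_models = train_plane_models(
            volumes, con_labels, ConversionMethod.MID, con_config,
            policy, window, log=log,
        )
        modules["global"] = build_contrast_module(global_models)
        for ordinal, part in enumerate(sorted(set(body_labels))):
            idx = [i for i, b in enumerate(body_labels) if b == part]
            sub_config = TrainConfig(**{
                **con_config.__dict__,
                "seed": (con_config.seed + 9973 * (ordinal + 1)) % (2**31),
            })
            part_models = train_plane_models(
                [volumes[i] for i in idx], [con_labels[i] for i in idx],
                ConversionMethod.MID, sub_config, policy, window, log=log,
            )
            modules[part] = build_contrast_module(part_models)
        return body_module, modules
    con_models = train_plane_models(
        volumes, con_labels, ConversionMethod.MID, con_config,
        policy, window, log=log,
    )
    return body_module, build_contrast_module(con_models)


def classify_volumes(
    volumes,
    body_module: EnsembleConfig,
    contrast_modules,
    window: WindowParams = WindowParams(),
    thumbnail_dir=None,
) -> list[QCResult]:
    """Run the end-to-end QC classification on each volume."""
    return [
        run_imageqc(v, body_module, contrast_modules, window, thumbnail_dir)
        for v in volumes
    ]
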