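"""Volume → 2D representative images → normalized classifier inputs.

A CT volume is collapsed along one of the three anatomical axes by one of
three conversion methods, giving nine representative images per series:

* **MIP** — per-ray maximum intensity along the collapsed axis;
* **AIP** — per-ray arithmetic mean along the collapsed axis;
* **MID** — the single central slice, index ``floor(n/2)`` (0-based).

Axial collapses the slice (z) axis, sagittal the column (left–right, x)
axis, and coronal the row (anterior–posterior, y) axis. Projections are
computed in raw HU, then windowed (default level 50 HU, width 1000 HU) to
[0,1], resized to 512×512 with bilinear interpolation for PNG export, and
replicated into three identical channels at 299×299 as classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from skimage.transform import resize as _skimage_resize

from .volume_io import CTVolume, write_png

__all__ = [
    "Plane",
    "ConversionMethod",
    "WindowParams",
    "Projection2D",
    "PNG_SIZE",
    "MODEL_INPUT_SIZE",
    "project",
    "apply_window",
    "resize",
    "to_model_input",
    "convert_series",
    "representative_images",
]

PNG_SIZE = 512
MODEL_INPUT_SIZE = 299


class Plane(str, Enum):
    AXIAL = "axial"
    SAGITTAL = "sagittal"
    CORONAL = "coronal"

    @property
    def axis(self) -> int:
        """Volume axis collapsed by this plane (volume is [z, y, x])."""
        return {"axial": 0, "coronal": 1, "sagittal": 2}[self.value]


class ConversionMethod(str, Enum):
    MIP = "MIP"
    AIP = "AIP"
    MID = "MID"


@dataclass(frozen=True)
class WindowParams:
    """HU display window: [level − width/2, level + width/2] → [0,1]."""

    level: float = 50.0
    width: float = 1000.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


@dataclass
class Projection2D:
    """A 2D representative image with provenance."""

    pixels: np.ndarray
    state: str  # "raw_hu" | "windowed"
    method: ConversionMethod
    plane: Plane
    series_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("projection pixels must be finite")
        if self.state == "windowed" and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("windowed pixels must lie in [0,1]")


def project(volume: CTVolume, method: ConversionMethod, plane: Plane) -> Projection2D:
    """Collapse *volume* along the plane's axis with the given method (raw HU)."""
    method = ConversionMethod(method)
    plane = Plane(plane)
    axis = plane.axis
    if method is ConversionMethod.MIP:
        pixels = volume.voxels.max(axis=axis)
    elif method is ConversionMethod.AIP:
        pixels = volume.voxels.mean(axis=axis)
    else:
        mid = volume.voxels.shape[axis] // 2
        pixels = np.take(volume.voxels, mid, axis=axis)
    return Projection2D(pixels, "raw_hu", method, plane, volume.series_id)


def apply_window(image: Projection2D, w: WindowParams = WindowParams()) -> Projection2D:
    """Linearly map HU through the display window, clamping to [0,1].

    ``v ↦ clamp((v − (level − width/2)) / width, 0, 1)``; with the defaults
    (level 50, width 1000): −450 HU → 0, 50 HU → 0.5, 550 HU → 1.
    """
    if image.state != "raw_hu":
        raise ValueError("apply_window expects a raw_hu projection")
    lo = w.level - w.width / 2.0
    pixels = np.clip((image.pixels - lo) / w.width, 0.0, 1.0)
    return Projection2D(pixels, "windowed", image.method, image.plane, image.series_id)


def resize(image: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize of a [0,1] image to target×target, clipped to [0,1]."""
    if target < 1:
        raise ValueError("target size must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.shape == (target, target):
        return image
    out = _skimage_resize(
        image, (target, target), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def to_model_input(image: np.ndarray, size: int = MODEL_INPUT_SIZE) -> np.ndarray:
    """Resize a windowed [0,1] image and copy it into three identical channels."""
    single = resize(image, size)
    return np.repeat(single[:, :, None], 3, axis=2)


def representative_images(
    volume: CTVolume, w: WindowParams = WindowParams()
) -> dict[tuple[ConversionMethod, Plane], Projection2D]:
    """All nine windowed (method, plane) representative images of a volume."""
    return {
        (m, p): apply_window(project(volume, m, p), w)
        for m in ConversionMethod
        for p in Plane
    }


def convert_series(
    volume: CTVolume,
    method: ConversionMethod,
    plane: Plane,
    w: WindowParams = WindowParams(),
    out_dir: str | Path | None = None,
) -> tuple[Path | None, np.ndarray]:
    """Full conversion chain for one (method, plane) combination.

    project → window → resize(512) → PNG (named
    ``{series_id}_{method}_{plane}.png`` when *out_dir* is given), plus the
    299×299×3 model input. Returns ``(png_path_or_None, model_input)``.
    """
    windowed = apply_window(project(volume, method, plane), w)
    png_image = resize(windowed.pixels, PNG_SIZE)
    png_path = None
    if out_dir is not None:
        name = f"{volume.series_id}_{ConversionMethod(method).value}_{Plane(plane).value}.png"
        png_path = write_png(png_image, Path(out_dir) / name)
    return png_path, to_model_input(png_image)
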