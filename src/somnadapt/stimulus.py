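"""Face-distortion stimulus continuum.

Figural face after-effects are induced with a graded continuum of
configurally distorted versions of a single frontal face: six gradually
compressed versions (k = -6 .. -1), the original (k = 0), and six gradually
extended versions (k = +1 .. +6).  The distortion is a radial warp about the
face midpoint with a Gaussian falloff: a source pixel at radius r from the
center is displaced to radius

    r' = r * (1 + strength * k * exp(-r**2 / (2 * falloff**2)))

so positive k pushes inner facial features outward ("extended") and negative
k pulls them inward ("compressed"), while the image border is essentially
untouched.  The warp is rendered by inverse mapping with bilinear
interpolation so the output has no holes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import map_coordinates

__all__ = [
    "LEVELS",
    "FaceImage",
    "DistortionContinuum",
    "displacement_field",
    "warp_face",
    "generate_continuum",
    "save_continuum",
    "load_continuum",
]

#: Distortion levels of the continuum, compressed (-6) to extended (+6).
LEVELS = tuple(range(-6, 7))

#: Default radial gain per distortion unit.
DEFAULT_STRENGTH = 0.02

#: Default Gaussian falloff radius as a fraction of the image min-dimension.
DEFAULT_FALLOFF_FRAC = 0.30


@dataclass
class FaceImage:
    """A raster face image plus the coordinates of the face midpoint.

    ``pixels`` is a 2-D (grayscale) or 3-D (H x W x channels) array;
    ``center`` is the (x, y) pixel position the radial warp is anchored at
    (defaults to the image center).
    """

    pixels: np.ndarray
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D or 3-D array")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image has zero area")
        if self.center is None:
            self.center = ((self.width - 1) / 2.0, (self.height - 1) / 2.0)
        cx, cy = self.center
        if not (0 <= cx < self.width and 0 <= cy < self.height):
            raise ValueError("center must lie inside the image bounds")

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @classmethod
    def open(cls, path: str | Path, center: tuple[float, float] | None = None) -> "FaceImage":
        return cls(np.asarray(Image.open(path)), center=center)

    def save(self, path: str | Path) -> None:
        arr = self.pixels
        if arr.dtype != np.uint8:
            arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)


@dataclass
class DistortionContinuum:
    """The 13-level map k -> FaceImage derived from one source face."""

    levels: dict[int, FaceImage]
    source: FaceImage
    strength: float = DEFAULT_STRENGTH
    falloff: float = field(default=0.0)

    def __post_init__(self) -> None:
        if sorted(self.levels) != list(LEVELS):
            raise ValueError("continuum must contain exactly levels -6..+6")
        dims = {(im.width, im.height) for im in self.levels.values()}
        if len(dims) != 1:
            raise ValueError("all levels must share dimensions")

    def __getitem__(self, k: int) -> FaceImage:
        return self.levels[k]

    def __len__(self) -> int:
        return len(self.levels)


def _check_level(k: int) -> int:
    k = int(k)
    if not (LEVELS[0] <= k <= LEVELS[-1]):
        raise ValueError(f"distortion level k={k} outside [-6, +6]")
    return k


def _resolve_falloff(image: FaceImage, falloff: float | None) -> float:
    if falloff is None:
        return DEFAULT_FALLOFF_FRAC * min(image.width, image.height)
    if falloff <= 0:
        raise ValueError("falloff must be > 0")
    return float(falloff)


def displacement_field(
    shape: tuple[int, int],
    center: tuple[float, float],
    k: int,
    strength: float = DEFAULT_STRENGTH,
    falloff: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward displacement (dx, dy) of every pixel for level ``k``.

    The radial map sends radius r to r * (1 + strength*k*exp(-r^2/(2 f^2)));
    the returned arrays are the Cartesian components of that displacement.
    Used both by the renderer's oracle tests and for monotonicity checks:
    the mean absolute displacement is linear in \\|k\\| for fixed strength
    and falloff.
    """
    k = _check_level(k)
    h, w = shape
    cx, cy = center
    y, x = np.mgrid[0:h, 0:w].astype(float)
    dxc, dyc = x - cx, y - cy
    r2 = dxc * dxc + dyc * dyc
    gain = strength * k * np.exp(-r2 / (2.0 * falloff**2))
    return dxc * gain, dyc * gain


def warp_face(
    image: FaceImage,
    k: int,
    strength: float = DEFAULT_STRENGTH,
    falloff: float | None = None,
) -> FaceImage:
    """Warp a face to distortion level ``k``.

    Positive k extends the face (features pushed radially outward), negative
    k compresses it; k = 0 returns a pixel-identical copy.  The forward
    radial map is inverted numerically on a dense monotone radius table and
    the output is sampled from the source by bilinear interpolation
    (inverse mapping; border pixels clamp).
    """
    k = _check_level(k)
    if strength <= 0:
        raise ValueError("strength must be > 0")
    falloff = _resolve_falloff(image, falloff)

    if k == 0:
        # the radial map is the identity; skip interpolation so the level-0
        # image is bit-exact
        return FaceImage(image.pixels.copy(), center=image.center)

    h, w = image.height, image.width
    cx, cy = image.center

    # forward radial map g(r); monotone for strength*|k| well below 1
    r_max = float(np.hypot(max(cx, w - 1 - cx), max(cy, h - 1 - cy))) + 1.0
    r_grid = np.linspace(0.0, r_max, 4096)
    g = r_grid * (1.0 + strength * k * np.exp(-(r_grid**2) / (2.0 * falloff**2)))
    if np.any(np.diff(g) <= 0):
        raise ValueError("warp is not invertible; reduce strength or |k|")

    y, x = np.mgrid[0:h, 0:w].astype(float)
    dxc, dyc = x - cx, y - cy
    r_out = np.hypot(dxc, dyc)
    r_in = np.interp(r_out, g, r_grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_out > 0, r_in / np.where(r_out > 0, r_out, 1.0), 1.0)
    xs = cx + dxc * scale
    ys = cy + dyc * scale

    src = image.pixels
    if src.ndim == 2:
        out = map_coordinates(src.astype(float), [ys, xs], order=1, mode="nearest")
    else:
        out = np.stack(
            [
                map_coordinates(src[..., c].astype(float), [ys, xs], order=1, mode="nearest")
                for c in range(src.shape[2])
            ],
            axis=-1,
        )
    if np.issubdtype(src.dtype, np.integer):
        info = np.iinfo(src.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(src.dtype)
    return FaceImage(out, center=image.center)


def generate_continuum(
    image: FaceImage,
    strength: float = DEFAULT_STRENGTH,
    falloff: float | None = None,
) -> DistortionContinuum:
    """Build the full 13-level compressed/extended continuum from one face."""
    falloff = _resolve_falloff(image, falloff)
    levels = {k: warp_face(image, k, strength=strength, falloff=falloff) for k in LEVELS}
    return DistortionContinuum(levels=levels, source=image, strength=strength, falloff=falloff)


def save_continuum(cont: DistortionContinuum, directory: str | Path) -> Path:
    """Write the 13 PNGs plus a JSON manifest of the warp parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, im in cont.levels.items():
        im.save(directory / f"face_k{k}.png")
    manifest = {
        "levels": list(LEVELS),
        "strength": cont.strength,
        "falloff": cont.falloff,
        "center": list(cont.source.center),
        "width": cont.source.width,
        "height": cont.source.height,
        "files": {str(k): f"face_k{k}.png" for k in LEVELS},
    }
    path = directory / "continuum.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_continuum(directory: str | Path) -> DistortionContinuum:
    directory = Path(directory)
    manifest = json.loads((directory / "continuum.json").read_text())
    center = tuple(manifest["center"])
    levels = {
        int(k): FaceImage.open(directory / fname, center=center)
        for k, fname in manifest["files"].items()
    }
    if manifest.get("width") != levels[0].width or manifest.get("height") != levels[0].height:
        warnings.warn("manifest dimensions disagree with the PNGs on disk")
    return DistortionContinuum(
        levels=levels,
        source=levels[0],
        strength=manifest["strength"],
        falloff=manifest["falloff"],
    )
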