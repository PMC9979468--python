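"""Fundus image loading, 2-D channel extraction and resizing.

A colour fundus photograph enters the pipeline as a ``RawImage`` (an RGB
intensity grid in [0, 1] with a class label inferred from its directory).
Downstream stages operate on a single 2-D channel representation — the red,
green or blue plane, or a luma grayscale — resized to a common analysis grid
(300x300 by default) so every image contributes the same number of scalars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

#: Recognised class-directory names (lowercased) mapped to canonical labels.
KNOWN_LABELS = {"healthy": "healthy", "normal": "healthy", "glaucoma": "glaucoma"}

#: Channel tokens: blue/green/red planes and luma grayscale.
CHANNELS = ("BC", "GC", "RC", "GS")

#: ITU BT.601 luma weights for the grayscale representation (R, G, B).
GRAYSCALE_WEIGHTS = (0.2989, 0.5870, 0.1140)

#: Default analysis grid.
DEFAULT_TARGET = (300, 300)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


class ConfigurationError(ValueError):
    """Raised for invalid channel tokens, sizes or parameter values."""


@dataclass
class RawImage:
    """An RGB fundus photograph with intensities in [0, 1].

    Attributes
    ----------
    pixels : ndarray, shape (rows, cols, 3)
        Non-negative intensities in [0, 1].
    label : str
        ``"healthy"``, ``"glaucoma"`` or ``"unlabelled"``.
    source_id : str
        File path or phantom seed tag identifying the image's origin.
    """

    pixels: np.ndarray
    label: str = "unlabelled"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"RawImage requires a (rows, cols, 3) grid, got {self.pixels.shape}"
            )
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class ChannelImage:
    """A single 2-D channel representation of a fundus image."""

    pixels: np.ndarray
    channel: str
    label: str = "unlabelled"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"ChannelImage requires a 2-D grid, got {self.pixels.shape}")
        if self.channel not in CHANNELS:
            raise ConfigurationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _label_from_path(path: Path) -> str:
    parent = path.parent.name.lower()
    return KNOWN_LABELS.get(parent, "unlabelled")


def load_image(path: str | Path) -> RawImage:
    """Load a PNG (or equivalent raster) file as a ``RawImage``.

    Intensities are rescaled to [0, 1].  The class label is inferred from the
    enclosing directory name when it matches a known class ("healthy",
    "normal", "glaucoma"); otherwise the image is unlabelled.  Single-plane
    grayscale input is accepted and replicated to three planes with a warning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "P", "CMYK", "LA"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    arr = arr.astype(np.float64)
    if arr.dtype != np.float64:  # pragma: no cover - defensive
        arr = np.asarray(arr, dtype=np.float64)
    # 8-bit and 16-bit rasters rescale by their nominal maximum.
    if arr.max(initial=0.0) > 1.0:
        arr = arr / (65535.0 if arr.max() > 255.0 else 255.0)

    if arr.ndim == 2:
        logger.warning("%s is single-plane; replicating to three channels", path)
        arr = np.stack([arr, arr, arr], axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"{path}: unsupported raster layout with shape {arr.shape}")

    return RawImage(np.clip(arr, 0.0, 1.0), label=_label_from_path(path), source_id=str(path))


def extract_channel(img: RawImage, channel: str) -> ChannelImage:
    """Extract one 2-D representation: an R/G/B plane or the luma grayscale.

    Grayscale uses the BT.601 weights (0.2989, 0.5870, 0.1140).
    """
    if channel not in CHANNELS:
        raise ConfigurationError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if channel == "GS":
        w = GRAYSCALE_WEIGHTS
        plane = w[0] * img.pixels[..., 0] + w[1] * img.pixels[..., 1] + w[2] * img.pixels[..., 2]
    else:
        plane = img.pixels[..., {"RC": 0, "GC": 1, "BC": 2}[channel]]
    return ChannelImage(plane.copy(), channel, label=img.label, source_id=img.source_id)


def resize_image(ch: ChannelImage, target: tuple[int, int] = DEFAULT_TARGET) -> ChannelImage:
    """Resize a channel image to ``target`` with bicubic interpolation.

    Anti-aliasing is applied when downscaling; values are clipped back into
    [0, 1] (bicubic interpolation can overshoot near edges).
    """
    rows, cols = int(target[0]), int(target[1])
    if rows <= 0 or cols <= 0:
        raise ConfigurationError(f"target size must be positive, got {target}")
    if ch.size == (rows, cols):
        return ChannelImage(ch.pixels.copy(), ch.channel, label=ch.label, source_id=ch.source_id)
    shrinking = rows < ch.size[0] or cols < ch.size[1]
    out = _sk_resize(
        ch.pixels, (rows, cols), order=3, mode="reflect",
        anti_aliasing=shrinking, preserve_range=True,
    )
    return ChannelImage(
        np.clip(out, 0.0, 1.0), ch.channel, label=ch.label, source_id=ch.source_id
    )


def iter_image_paths(root: str | Path) -> list[Path]:
    """Deterministic (lexicographically sorted) recursive listing of images."""
    root = Path(root)
    return sorted(
        p for p in root.rglob("*") if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
    )


def preprocess_dataset(
    root: str | Path,
    channel: str = "GS",
    target: tuple[int, int] = DEFAULT_TARGET,
) -> list[ChannelImage]:
    """Load, channel-extract and resize every image under ``root``.

    ``root`` holds class-named subdirectories (the RIM-ONE DL layout).
    Traversal is lexicographic so repeated runs produce identical output
    order.  Non-image files are skipped with a warning.
    """
    paths = iter_image_paths(root)
    out: list[ChannelImage] = []
    counts: dict[str, int] = {}
    for path in paths:
        try:
            raw = load_image(path)
        except IOError as exc:
            logger.warning("skipping unreadable file %s (%s)", path, exc)
            continue
        out.append(resize_image(extract_channel(raw, channel), target))
        counts[raw.label] = counts.get(raw.label, 0) + 1
    if not out:
        raise IOError(f"no images found under {root}")
    logger.info("preprocessed %d images from %s: %s", len(out), root, counts)
    return out


def dataset_manifest(images: list[ChannelImage]):
    """Manifest rows (source_id, label, channel, rows, cols) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "source_id": im.source_id,
                "label": im.label,
                "channel": im.channel,
                "rows": im.size[0],
                "cols": im.size[1],
            }
            for im in images
        ]
    )
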