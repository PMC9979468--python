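"""Synthetic fundus phantoms: two-class labelled retina-like test images.

The generator emulates the gross geometry of a colour fundus photograph —
an orange-tinted background with an illumination tilt, a bright circular
optic disc containing a brighter central cup, dark vessel curves radiating
through the disc, and pixel noise — at varying native sizes so the resize
stage is always exercised.

The class-separating latent is the cup-to-disc diameter ratio (CDR): an
enlarged cup and a paler neuroretinal rim are the classical glaucoma markers,
so glaucoma phantoms draw their CDR from a higher-mean distribution and
receive a rim brightness shift.  Setting the two CDR means equal and the rim
shift to zero makes the class distributions identical, which gives the test
suite a null condition where any classifier must perform at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import RawImage

LABELS = ("healthy", "glaucoma")

# Render palette (R, G, B in [0, 1]).
_BACKGROUND = np.array([0.80, 0.42, 0.20])
_DISC = np.array([0.95, 0.80, 0.50])
_CUP = np.array([0.99, 0.93, 0.72])
_VESSEL = np.array([0.45, 0.12, 0.08])


@dataclass(frozen=True)
class PhantomParams:
    """Parameters controlling phantom geometry and class separation.

    ``cdr_healthy``/``cdr_glaucoma`` are the per-class mean cup-to-disc
    diameter ratios; ``cdr_sd`` is the between-subject spread (draws are
    truncated to (0.05, 0.95)).  ``rim_pallor_delta`` brightens the
    neuroretinal rim of glaucoma phantoms.  Native sizes are drawn uniformly
    per image from ``size_range`` (pixels per side).
    """

    size_range: tuple[int, int] = (400, 900)
    disc_radius_frac: float = 0.16
    cdr_healthy: float = 0.30
    cdr_glaucoma: float = 0.65
    cdr_sd: float = 0.08
    rim_pallor_delta: float = 0.10
    n_vessels: int = 6
    noise_sd: float = 0.02
    illumination_grad: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cdr_healthy < 1.0 and 0.0 < self.cdr_glaucoma < 1.0):
            raise ValueError("CDR means must lie in (0, 1)")
        if self.cdr_healthy > self.cdr_glaucoma:
            raise ValueError("cdr_healthy must not exceed cdr_glaucoma")
        if not (0.0 < self.disc_radius_frac < 0.5):
            raise ValueError("disc_radius_frac must lie in (0, 0.5)")
        if self.noise_sd < 0 or self.cdr_sd < 0:
            raise ValueError("spreads must be non-negative")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid size_range {self.size_range}")


@dataclass
class LabelledImageSet:
    """A generated two-class phantom collection with its drawing record."""

    images: list[RawImage]
    params: PhantomParams
    class_counts: tuple[int, int]  # (n_healthy, n_glaucoma)
    drawn_cdr: list[float] = field(default_factory=list)

    def manifest(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "source_id": im.source_id,
                    "label": im.label,
                    "cdr": cdr,
                    "rows": im.shape[0],
                    "cols": im.shape[1],
                }
                for im, cdr in zip(self.images, self.drawn_cdr)
            ]
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = 0.05, hi: float = 0.95) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _soft_disc(rr: np.ndarray, cc: np.ndarray, center: tuple[float, float],
               radius: float, softness: float) -> np.ndarray:
    """Smoothed indicator of a disc (1 inside, 0 outside, ~softness px edge)."""
    d = np.hypot(rr - center[0], cc - center[1])
    return 1.0 / (1.0 + np.exp((d - radius) / max(softness, 1e-6)))


def _vessel_canvas(shape: tuple[int, int], center: tuple[float, float],
                   n_vessels: int, rng: np.random.Generator) -> np.ndarray:
    """Soft mask of dark vessel curves radiating from the disc centre."""
    rows, cols = shape
    canvas = np.zeros(shape)
    if n_vessels == 0:
        return canvas
    width = max(1.2, 0.006 * rows)
    n_pts = 4 * max(rows, cols)
    t = np.linspace(0.0, 1.0, n_pts)
    reach = 0.75 * np.hypot(rows, cols) / 2.0
    for _ in range(n_vessels):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        curv = rng.normal(0.0, 0.6)        # angular drift: smooth curvature
        wobble = rng.normal(0.0, 0.15)
        ang = theta + curv * t + wobble * np.sin(2.5 * np.pi * t)
        radial = reach * t
        pr = center[0] + radial * np.sin(ang)
        pc = center[1] + radial * np.cos(ang)
        keep = (pr >= 0) & (pr < rows) & (pc >= 0) & (pc < cols)
        canvas[pr[keep].astype(int), pc[keep].astype(int)] = 1.0
    # soften the rasterized curves to the vessel width
    from scipy.ndimage import gaussian_filter

    canvas = gaussian_filter(canvas, sigma=width)
    peak = canvas.max()
    if peak > 0:
        canvas = np.clip(canvas / (0.5 * peak), 0.0, 1.0)
    return canvas


def generate_phantom(params: PhantomParams, label: str,
                     stream: np.random.Generator) -> RawImage:
    """Render one labelled phantom using draws from ``stream``.

    All geometry (native size, disc position, CDR, vessel paths, noise) comes
    from ``stream``, so an identically seeded generator reproduces the image
    bit for bit.  The label enters only through the CDR distribution and the
    rim pallor shift, keeping zero-separation parameter settings class-blind.
    """
    if label not in LABELS:
        raise ValueError(f"invalid label {label!r}; expected one of {LABELS}")

    lo, hi = params.size_range
    rows = int(stream.integers(lo, hi + 1))
    cols = int(stream.integers(lo, hi + 1))
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)

    # illumination tilt: linear brightness gradient across a random direction
    phi = stream.uniform(0.0, 2.0 * np.pi)
    proj = (rr - rows / 2) * np.sin(phi) + (cc - cols / 2) * np.cos(phi)
    span = np.abs(proj).max() or 1.0
    illum = 1.0 + params.illumination_grad * proj / (2.0 * span)

    disc_r = params.disc_radius_frac * rows
    center = (
        rows / 2 + stream.uniform(-0.08, 0.08) * rows,
        cols / 2 + stream.uniform(-0.08, 0.08) * cols,
    )

    mean_cdr = params.cdr_healthy if label == "healthy" else params.cdr_glaucoma
    cdr = _truncated_normal(stream, mean_cdr, params.cdr_sd)
    cup_r = cdr * disc_r
    cup_center = (
        center[0] + stream.uniform(-0.05, 0.05) * disc_r,
        center[1] + stream.uniform(-0.05, 0.05) * disc_r,
    )

    edge = max(1.0, 0.0035 * rows)
    disc_mask = _soft_disc(rr, cc, center, disc_r, edge)
    cup_mask = _soft_disc(rr, cc, cup_center, cup_r, edge) if cup_r > 0 else 0.0

    disc_col = _DISC + (params.rim_pallor_delta if label == "glaucoma" else 0.0)
    img = np.empty((rows, cols, 3))
    for k in range(3):
        plane = _BACKGROUND[k] * illum
        plane = plane * (1 - disc_mask) + min(disc_col[k], 1.0) * disc_mask
        img[..., k] = plane * (1 - cup_mask) + _CUP[k] * cup_mask

    vessels = _vessel_canvas((rows, cols), center, params.n_vessels, stream)
    img = img * (1 - 0.8 * vessels[..., None]) + _VESSEL * 0.8 * vessels[..., None]

    if params.noise_sd > 0:
        img = img + stream.normal(0.0, params.noise_sd, size=img.shape)

    img = np.clip(img, 0.0, 1.0)
    tag = f"phantom:{label}:cdr={cdr:.4f}"
    out = RawImage(img, label=label, source_id=tag)
    out.drawn_cdr = cdr  # type: ignore[attr-defined]  # oracle bookkeeping
    return out


def _image_stream(seed: int, class_code: int, index: int) -> np.random.Generator:
    # per-image stream keyed by (seed, class, index): subsets reproduce
    # independently of generation order
    return np.random.default_rng(np.random.SeedSequence([seed, class_code, index]))


def generate_dataset(
    n_healthy: int,
    n_glaucoma: int,
    params: PhantomParams | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> LabelledImageSet:
    """Generate a labelled two-class phantom set (default class ratio 219:120).

    When ``out_dir`` is given, images are also written as 8-bit PNGs in the
    class-directory layout the preprocessing module reads, together with a
    ``manifest.csv`` recording the drawn CDR per image.
    """
    if n_healthy < 0 or n_glaucoma < 0:
        raise ValueError("class counts must be non-negative")
    params = params or PhantomParams()
    master = params.seed if seed is None else int(seed)

    images: list[RawImage] = []
    cdrs: list[float] = []
    for code, (label, n) in enumerate((("healthy", n_healthy), ("glaucoma", n_glaucoma))):
        for i in range(n):
            im = generate_phantom(params, label, _image_stream(master, code, i))
            im.source_id = f"phantom:{label}:{master}:{i:04d}"
            images.append(im)
            cdrs.append(im.drawn_cdr)  # type: ignore[attr-defined]

    dataset = LabelledImageSet(images, params, (n_healthy, n_glaucoma), cdrs)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def write_dataset(dataset: LabelledImageSet, out_dir: str | Path) -> list[Path]:
    """Write phantoms as PNGs under ``out_dir/<label>/`` plus a manifest CSV."""
    from PIL import Image

    out_dir = Path(out_dir)
    written: list[Path] = []
    counters: dict[str, int] = {}
    for im in dataset.images:
        idx = counters.get(im.label, 0)
        counters[im.label] = idx + 1
        d = out_dir / im.label
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{im.label}_{idx:04d}.png"
        Image.fromarray(np.round(im.pixels * 255.0).astype(np.uint8)).save(path)
        written.append(path)
    dataset.manifest().to_csv(out_dir / "manifest.csv", index=False)
    return written
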