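"""Instrument-comparison analytics for pre-aligned brightfield images.

Two whole-slide scanners imaging the same tissue can differ systematically
in brightness and colour balance (light source, optics).  These utilities
quantify that: normalized per-channel histograms of a common rectangular
region, the histogram mass falling into the staining-intensity zones
(strong/moderate/weak/negative+background, bounded by t1, t2, t0), and the
pixelwise intensity correspondence (Pearson r plus a mean mapping curve)
between two aligned monochrome images.  Registration itself is out of scope;
inputs must already be aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .categorization import CategoryThresholds
from .errors import DegenerateDataWarning, ValidationError

__all__ = [
    "ChannelHistograms",
    "ZoneAreas",
    "channel_histograms",
    "monochrome",
    "zone_areas",
    "intensity_correspondence",
    "CorrespondenceResult",
    "ZONE_NAMES",
]

ZONE_NAMES = ("strong", "moderate", "weak", "negative")
_CHANNELS = ("red", "green", "blue", "mono")


@dataclass(frozen=True)
class ChannelHistograms:
    """Normalized 256-bin histograms of a region, per colour channel + monochrome."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    mono: np.ndarray
    region: tuple[int, int, int, int] | None
    n_pixels: int

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass(frozen=True)
class ZoneAreas:
    """Histogram mass per staining zone, per channel; each channel sums to 1."""

    areas: dict  # channel -> {zone: mass}
    thresholds: CategoryThresholds

    def channel(self, name: str) -> dict:
        return self.areas[name]


def monochrome(image: np.ndarray, weights: tuple[float, float, float] | None = None) -> np.ndarray:
    """Monochrome image as the rounded (by default unweighted) mean of R, G, B."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValidationError(f"expected an HxWx3 image, got {img.shape}")
    if weights is None:
        mono = img.mean(axis=-1)
    else:
        w = np.asarray(weights, dtype=float)
        mono = img @ (w / w.sum())
    return np.clip(np.rint(mono), 0, 255).astype(np.uint8)


def channel_histograms(
    image: np.ndarray, rectangle: tuple[int, int, int, int] | None = None
) -> ChannelHistograms:
    """Normalized histograms of a rectangular region of an RGB image.

    ``rectangle`` is (row0, col0, row1, col1), half-open; ``None`` uses the
    whole image.  Each histogram has 256 bins and sums to 1.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValidationError(f"expected an HxWx3 RGB image, got {img.shape}")
    if rectangle is not None:
        r0, c0, r1, c1 = rectangle
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ValidationError(
                f"rectangle {rectangle} empty or outside image of shape {img.shape[:2]}"
            )
        img = img[r0:r1, c0:c1]
    n = img.shape[0] * img.shape[1]
    if n == 0:
        raise ValidationError("empty region")
    mono = monochrome(img)
    hists = {}
    for i, name in enumerate(("red", "green", "blue")):
        hists[name] = np.bincount(img[..., i].ravel(), minlength=256)[:256] / n
    hists["mono"] = np.bincount(mono.ravel(), minlength=256)[:256] / n
    return ChannelHistograms(
        red=hists["red"],
        green=hists["green"],
        blue=hists["blue"],
        mono=hists["mono"],
        region=rectangle,
        n_pixels=n,
    )


def zone_areas(hists: ChannelHistograms, thresholds: CategoryThresholds) -> ZoneAreas:
    """Histogram mass in the four intensity zones, per channel.

    Zone intervals reuse the categorization boundary convention: strong is
    value <= t1, moderate (t1, t2], weak (t2, t0], negative+background
    (t0, 255].  The four masses partition each channel's histogram.
    """
    bins = np.arange(256)
    zone_of = np.where(
        bins <= thresholds.t1,
        0,
        np.where(bins <= thresholds.t2, 1, np.where(bins <= thresholds.t0, 2, 3)),
    )
    areas = {}
    for name in _CHANNELS:
        h = hists.channel(name)
        areas[name] = {
            zone: float(h[zone_of == zi].sum()) for zi, zone in enumerate(ZONE_NAMES)
        }
    return ZoneAreas(areas=areas, thresholds=thresholds)


@dataclass(frozen=True)
class CorrespondenceResult:
    pearson_r: float
    #: curve[v] = mean intensity in B over pixels where A == v (NaN if unseen)
    curve: np.ndarray
    empty_levels: np.ndarray
    degenerate: bool = False


def intensity_correspondence(
    image_a: np.ndarray, image_b: np.ndarray
) -> CorrespondenceResult:
    """Pixelwise intensity correspondence between two aligned monochrome images.

    Returns the Pearson correlation over all pixel pairs and, for each
    intensity level v present in A, the mean intensity of B at those pixels.
    Constant input makes the correlation undefined (NaN, flagged).
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValidationError("images must be 2-D monochrome")
    av, bv = a.ravel(), b.ravel()
    degenerate = av.std() == 0 or bv.std() == 0
    if degenerate:
        warnings.warn(
            "constant image: correlation undefined", DegenerateDataWarning, stacklevel=2
        )
        r = float("nan")
    else:
        r = float(np.corrcoef(av, bv)[0, 1])
    ai = np.clip(np.rint(av).astype(int), 0, 255)
    sums = np.bincount(ai, weights=bv, minlength=256)
    counts = np.bincount(ai, minlength=256)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = sums / counts
    return CorrespondenceResult(
        pearson_r=r,
        curve=curve,
        empty_levels=np.flatnonzero(counts == 0),
        degenerate=degenerate,
    )
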