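"""Optical-density colour deconvolution for brightfield immunohistochemistry.

Brightfield stains absorb light, so transmitted intensity follows the
Beer-Lambert law: each stain contributes additively in optical density
(OD = -log10(I / I0)).  An RGB pixel is therefore a non-negative linear
combination of per-stain unit OD vectors, and stain amounts are recovered
by inverting that 3x3 system (Ruifrok-Johnston colour deconvolution).

All downstream analysis works on the "white pixel intensity" of a single
stain channel: the 0-255 brightness the image would have if only that
stain were present.  255 means no stain; low values mean strong staining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .errors import ValidationError

#: Guard added to intensities before the log so that a zero pixel stays finite.
LOG_EPS = 1.0 / 255.0

# Ruifrok-Johnston absorbance triplets for hematoxylin and DAB.  The third
# (residual) column is the conventional non-negative completion
# r_i = sqrt(1 - h_i^2 - d_i^2), normalized to unit length.
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.268, 0.570, 0.776)


def _residual_column(a, b):
    comp = np.sqrt(np.clip(1.0 - np.asarray(a) ** 2 - np.asarray(b) ** 2, 0.0, None))
    return comp / np.linalg.norm(comp)


@dataclass(frozen=True)
class StainVectors:
    """A 3x3 matrix whose columns are unit optical-density vectors, one per stain.

    Parameters
    ----------
    matrix
        Shape (3, 3); column ``s`` is the OD triplet of stain ``s``.
    names
        Stain names in column order.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError(f"stain columns must be unit length, norms={norms}")
        if np.any(m < -1e-12):
            raise ValidationError("stain vector entries must be non-negative")
        if not np.isfinite(np.linalg.cond(m)):
            raise ValidationError(f"stain matrix is singular: {m}")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @classmethod
    def hdab(cls) -> "StainVectors":
        """The published hematoxylin-DAB pair with a computed residual column."""
        m = np.column_stack([_HEMATOXYLIN, _DAB, _residual_column(_HEMATOXYLIN, _DAB)])
        m = m / np.linalg.norm(m, axis=0, keepdims=True)
        return cls(m)

    @classmethod
    def from_mapping(cls, rows: Mapping[str, object]) -> "StainVectors":
        """Build from ``{name: [od_r, od_g, od_b], ...}`` (column normalization applied)."""
        names = tuple(rows.keys())
        if len(names) != 3:
            raise ValidationError(f"expected exactly 3 stains, got {names}")
        m = np.column_stack([np.asarray(rows[n], dtype=float) for n in names])
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms == 0):
            raise ValidationError("zero-length stain vector")
        return cls(m / norms, names=names)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path) -> "StainVectors":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        return {n: [float(v) for v in self.matrix[:, i]] for i, n in enumerate(self.names)}


def rgb_to_od(image: np.ndarray, i0: float = 255.0, eps: float = LOG_EPS) -> np.ndarray:
    """Convert an RGB image (or any channel stack) to optical density.

    OD_c = -log10((I_c + eps) / I0).  ``eps`` keeps zero pixels finite;
    values brighter than I0 give slightly negative OD, which is preserved.
    """
    if i0 <= 0:
        raise ValidationError(f"reference white i0 must be positive, got {i0}")
    img = np.asarray(image, dtype=float)
    return -np.log10((img + eps) / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Exact inverse of the OD transform (without the eps guard): I = I0 * 10**(-OD).

    Returns floats; callers quantize to uint8 themselves when composing images.
    """
    if i0 <= 0:
        raise ValidationError(f"reference white i0 must be positive, got {i0}")
    return i0 * np.power(10.0, -np.asarray(od, dtype=float))


def deconvolve(od: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Unmix an OD image into per-stain concentrations.

    Solves ``vectors.matrix @ c = od`` per pixel.  Concentrations may come out
    slightly negative under noise; they are clipped only when converting to
    white intensity, so diagnostics keep the raw values.
    """
    vectors = vectors or StainVectors.hdab()
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValidationError(f"OD image must have 3 channels, got shape {od.shape}")
    flat = od.reshape(-1, 3)
    conc = flat @ vectors.inverse.T
    return conc.reshape(od.shape)


def compose_od(concentrations: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Forward Beer-Lambert model: OD = vectors.matrix @ c per pixel."""
    vectors = vectors or StainVectors.hdab()
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape[-1] != 3:
        raise ValidationError(f"concentration image must have 3 channels, got {conc.shape}")
    return (conc.reshape(-1, 3) @ vectors.matrix.T).reshape(conc.shape)


def concentration_to_white(concentration: np.ndarray) -> np.ndarray:
    """Map a single-stain concentration image to 0-255 white pixel intensity.

    w = round(clip(255 * 10**(-max(c, 0)), 0, 255)); c = 0 gives 255 (no stain)
    and the map is monotone decreasing in c.
    """
    c = np.clip(np.asarray(concentration, dtype=float), 0.0, None)
    w = np.clip(255.0 * np.power(10.0, -c), 0.0, 255.0)
    return np.rint(w).astype(np.uint8)


def white_to_concentration(white: np.ndarray, floor: float = 0.25) -> np.ndarray:
    """Inverse of :func:`concentration_to_white` on floats: c = -log10(w / 255).

    ``floor`` bounds the white intensity away from zero so the concentration
    stays finite; a floor of 0.25 still reconstructs to a white value of 0
    after uint8 rounding.
    """
    w = np.maximum(np.asarray(white, dtype=float), floor)
    return -np.log10(w / 255.0)


def separate_stains(
    rgb: np.ndarray,
    vectors: StainVectors | None = None,
    i0: float = 255.0,
) -> dict[str, np.ndarray]:
    """RGB image -> per-stain white-intensity images (uint8), keyed by stain name."""
    vectors = vectors or StainVectors.hdab()
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValidationError(f"expected an HxWx3 RGB image, got shape {rgb.shape}")
    conc = deconvolve(rgb_to_od(rgb, i0=i0), vectors)
    return {name: concentration_to_white(conc[..., i]) for i, name in enumerate(vectors.names)}
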