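"""Ground-truthed synthetic H-DAB data.

Three generators make the whole pipeline testable without clinical slides:

* :func:`generate_mixture_sample` — white-intensity samples from a Gaussian
  mixture, the statistical structure the categorization model assumes.
* :func:`generate_ihc_image` — a brightfield tile of non-overlapping
  elliptical nuclei.  Every nucleus carries hematoxylin; DAB-positive nuclei
  additionally carry a DAB amount chosen so that colour deconvolution (with
  the same stain vectors used for composition) reads back the cell's assigned
  white intensity.  Composition uses the Beer-Lambert forward model, so the
  analysis chain inverts the generator exactly up to uint8 rounding.
* :func:`generate_timecourse` — marker measurements over decalcification
  times 0/1/6/24 h with case-level baselines and multiplicative field noise,
  the structure of a slide-averaged decalcification study.

Membrane-vs-nucleus stain localization and tissue texture are deliberately
not simulated: the quantification method consumes intensity statistics, not
morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .categorization import CategoryThresholds, MixtureModel, categorize_intensities
from .errors import PlacementError, ValidationError
from .stains import StainVectors, compose_od, white_to_concentration

__all__ = [
    "SyntheticImageSpec",
    "GroundTruth",
    "DEFAULT_DAB_MIXTURE",
    "generate_mixture_sample",
    "generate_ihc_image",
    "generate_timecourse",
    "DECAL_TIMES_H",
]

#: Decalcification time points (hours) used throughout the study design.
DECAL_TIMES_H = (0, 1, 6, 24)

#: Default DAB white-intensity mixture: strong / moderate / weak components.
DEFAULT_DAB_MIXTURE = MixtureModel(
    weights=(0.3, 0.4, 0.3), means=(40.0, 130.0, 205.0), sds=(15.0, 25.0, 12.0)
)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic H-DAB field of view.

    Defaults emulate a calibration field: ~2,000 tumour nuclei with
    heterogeneous DAB staining drawn from a three-component mixture on
    [0, 230] white intensity, 65% of cells DAB-negative (hematoxylin only).
    """

    height: int = 2048
    width: int = 2048
    n_cells: int = 2000
    radius_range: tuple[float, float] = (6.0, 12.0)
    dab_mixture: MixtureModel = field(default_factory=lambda: DEFAULT_DAB_MIXTURE)
    negative_fraction: float = 0.65
    hematoxylin_mean: float = 120.0
    hematoxylin_sd: float = 8.0
    background_white: int = 255
    noise_sd: float = 0.0
    seed: int = 0
    #: Positive DAB white intensities are clipped to this range (upper end =
    #: the background cutoff, so every positive cell is below background).
    positive_clip: tuple[float, float] = (0.0, 230.0)
    #: Minimum blank gap (pixels) enforced between nuclei.
    separation: int = 2
    max_attempts_per_cell: int = 100

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValidationError("cell count must be >= 0")
        if self.height <= 0 or self.width <= 0:
            raise ValidationError("image dimensions must be positive")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid radius range {self.radius_range}")
        if not (0.0 <= self.negative_fraction <= 1.0):
            raise ValidationError("negative_fraction must be in [0, 1]")
        if not (0 < self.background_white <= 255):
            raise ValidationError("background_white must be in (0, 255]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        mu = self.dab_mixture.means
        if np.any(mu < 0) or np.any(mu > 255):
            raise ValidationError("mixture means must lie in [0, 255]")

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticImageSpec":
        data = dict(data)
        if "dab_mixture" in data and not isinstance(data["dab_mixture"], MixtureModel):
            m = data["dab_mixture"]
            data["dab_mixture"] = MixtureModel(
                weights=m["weights"], means=m["means"], sds=m["sds"]
            )
        for key in ("radius_range", "positive_clip"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class GroundTruth:
    """Per-cell truth for a synthetic image.

    ``cells`` has one row per nonzero mask label: label, centroid, area,
    assigned category and white intensities.  ``thresholds`` are the analytic
    category thresholds of the generating mixture (t0 = upper positive clip),
    and categories are, by construction, the re-categorization of the
    assigned intensities under those thresholds.
    """

    label_mask: np.ndarray
    cells: pd.DataFrame
    mixture: MixtureModel
    thresholds: CategoryThresholds

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def percent_positive(self) -> float:
        if not len(self.cells):
            return float("nan")
        return 100.0 * float((self.cells["category"] != "negative").mean())


def generate_mixture_sample(
    model: MixtureModel, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw ``n`` white-intensity values from a Gaussian mixture, clipped to [0, 255].

    Each draw picks a component according to the weights, then samples that
    component's Gaussian.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValidationError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    comp = rng.choice(model.k, size=n, p=model.weights)
    draws = rng.normal(model.means[comp], model.sds[comp])
    return np.clip(draws, 0.0, 255.0)


def _place_nuclei(spec: SyntheticImageSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipses; returns the label mask."""
    shape = (spec.height, spec.width)
    mask = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    lo, hi = spec.radius_range
    margin = spec.separation
    placed = 0
    for label in range(1, spec.n_cells + 1):
        ok = False
        for _ in range(spec.max_attempts_per_cell):
            rr_rad = rng.uniform(lo, hi)
            cc_rad = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, np.pi)
            r0 = rng.uniform(hi + margin, spec.height - hi - margin)
            c0 = rng.uniform(hi + margin, spec.width - hi - margin)
            grow_r, grow_c = draw_ellipse(
                r0, c0, rr_rad + margin, cc_rad + margin, shape=shape, rotation=theta
            )
            if occupied[grow_r, grow_c].any():
                continue
            cell_r, cell_c = draw_ellipse(
                r0, c0, rr_rad, cc_rad, shape=shape, rotation=theta
            )
            if cell_r.size == 0:
                continue
            mask[cell_r, cell_c] = label
            occupied[grow_r, grow_c] = True
            placed += 1
            ok = True
            break
        if not ok:
            raise PlacementError(placed, spec.n_cells)
    return mask


def generate_ihc_image(
    spec: SyntheticImageSpec, vectors: StainVectors | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic H-DAB RGB tile and its ground truth.

    Returns the uint8 RGB image and a :class:`GroundTruth`.  With
    ``noise_sd = 0`` the only error source between assigned and deconvolved
    per-cell DAB white intensity is uint8 rounding (within +-1 on cell means).
    """
    vectors = vectors or StainVectors.hdab()
    rng = np.random.default_rng(spec.seed)
    mask = _place_nuclei(spec, rng)
    n = spec.n_cells

    # Deterministic negative count so the realized positive fraction is exact.
    n_neg = int(round(spec.negative_fraction * n))
    is_negative = np.zeros(n, dtype=bool)
    is_negative[:n_neg] = True
    rng.shuffle(is_negative)

    dab_white = np.full(n, np.nan)
    n_pos = n - n_neg
    if n_pos:
        draws = generate_mixture_sample(
            spec.dab_mixture, n_pos, seed=rng.integers(0, 2**31 - 1)
        )
        dab_white[~is_negative] = np.clip(draws, *spec.positive_clip)
    hema_white = np.clip(
        rng.normal(spec.hematoxylin_mean, spec.hematoxylin_sd, size=n), 20.0, 250.0
    )

    # Per-pixel stain concentrations (hematoxylin, DAB, residual).
    conc = np.zeros((spec.height, spec.width, 3))
    if n:
        cell_idx = mask - 1  # -1 where background
        inside = mask > 0
        c_h = white_to_concentration(hema_white)
        conc[..., 0][inside] = c_h[cell_idx[inside]]
        c_d = np.zeros(n)
        pos = ~is_negative
        c_d[pos] = white_to_concentration(dab_white[pos])
        conc[..., 1][inside] = c_d[cell_idx[inside]]

    rgb = 255.0 * np.power(10.0, -compose_od(conc, vectors))
    rgb[mask == 0] = float(spec.background_white)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    # Dithered quantization: floor(x + u), u ~ U[0, 1), is unbiased, so the
    # per-cell mean of the quantized image matches the assigned intensity even
    # though every pixel of a cell carries the same float value.  Deterministic
    # rounding would leave a systematic offset of up to ~1.3 grey levels.
    rgb = np.clip(rgb, 0.0, 255.0)
    rgb = np.floor(rgb + rng.uniform(0.0, 1.0, size=rgb.shape))
    rgb = np.clip(rgb, 0.0, 255.0).astype(np.uint8)

    thresholds = CategoryThresholds.from_mixture(
        spec.dab_mixture, t0=spec.positive_clip[1]
    )
    if n:
        cats = np.full(n, "negative", dtype=object)
        if n_pos:
            pos_cats, _ = categorize_intensities(dab_white[pos], thresholds)
            cats[pos] = pos_cats
        areas = np.bincount(mask.ravel(), minlength=n + 1)[1:]
        cells = pd.DataFrame(
            {
                "label": np.arange(1, n + 1),
                "area": areas,
                "category": cats.astype(str),
                "dab_white": dab_white,
                "hema_white": hema_white,
            }
        )
    else:
        cells = pd.DataFrame(
            columns=["label", "area", "category", "dab_white", "hema_white"]
        )
    truth = GroundTruth(
        label_mask=mask, cells=cells, mixture=spec.dab_mixture, thresholds=thresholds
    )
    return rgb, truth


def generate_timecourse(
    baseline_mean: float = 150.0,
    baseline_sd: float = 20.0,
    effects: Sequence[float] = (1.0, 0.85, 0.80, 0.80),
    field_cv: float = 0.05,
    n_cases: int = 9,
    n_fields: int = 5,
    seed: int | None = None,
    marker: str = "ER",
    times_h: Sequence[float] = DECAL_TIMES_H,
) -> pd.DataFrame:
    """Simulate a decalcification time course.

    ``value(case, time, field) = baseline_case * effect(time) * (1 + eps)``
    with ``baseline_case ~ N(baseline_mean, baseline_sd)`` and field noise
    ``eps ~ N(0, field_cv)``.  ``effects[0]`` must be 1 (time zero is the
    reference).  Defaults reproduce the study design: 9 cases, 5 fields,
    times 0/1/6/24 h, a 15% intensity loss at 1 h plateauing at 20%, and 5%
    between-field variability.

    Returns a tidy table with columns ``case, marker, time_h, field, value``.
    """
    effects = np.asarray(effects, dtype=float)
    times_h = tuple(times_h)
    if len(effects) != len(times_h):
        raise ValidationError("one effect per time point required")
    if effects[0] != 1.0:
        raise ValidationError("effects[0] must be 1 (time zero is the reference)")
    if field_cv < 0:
        raise ValidationError("field_cv must be >= 0")
    if n_cases < 1 or n_fields < 1:
        raise ValidationError("n_cases and n_fields must be >= 1")

    rng = np.random.default_rng(seed)
    baselines = np.clip(
        rng.normal(baseline_mean, baseline_sd, size=n_cases), 1e-6, None
    )
    rows = []
    for ci in range(n_cases):
        for ti, t in enumerate(times_h):
            noise = rng.normal(0.0, field_cv, size=n_fields) if field_cv > 0 else np.zeros(n_fields)
            vals = np.clip(baselines[ci] * effects[ti] * (1.0 + noise), 0.0, None)
            for fi in range(n_fields):
                rows.append((ci + 1, marker, t, fi + 1, vals[fi]))
    return pd.DataFrame(rows, columns=["case", "marker", "time_h", "field", "value"])


def validate_timecourse(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy time-course schema and value invariants; returns the table."""
    required = {"case", "marker", "time_h", "field", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"time-course table missing columns: {sorted(missing)}")
    if (table["value"] < 0).any():
        raise ValidationError("time-course measurements must be >= 0")
    return table
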