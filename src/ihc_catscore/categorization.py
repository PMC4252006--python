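"""Conversion of continuous DAB intensity to categorical staining scores.

The pipeline mirrors how a pathologist's ordinal grades (0, 1+, 2+, 3+) relate
to chromogen darkness.  Positive-pixel white intensities (0-255; low = dark =
strong staining) are modeled as a three-component Gaussian mixture — one
component each for strong, moderate and weak staining — fitted by
expectation-maximization with a k-means initialization.  The two intersection
points of adjacent weighted component densities, projected onto the intensity
axis, become the category thresholds t1 (strong/moderate) and t2
(moderate/weak).  The background cutoff t0 comes from global histogram
thresholding (Otsu) or an explicit override such as the conventional 230.

Category conventions used throughout the package (white-intensity scale):

====================  =======================
strong (3+)           value <= t1
moderate (2+)         t1 < value <= t2
weak (0/1+)           t2 < value <= t0
negative/background   value > t0
====================  =======================

The "<= goes to the stronger side" boundary rule matches interval scoring
schemes that quote e.g. strong = 0-85, moderate = 86-180, weak = 181-230.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ComponentCollapseError, DegenerateDataWarning, ValidationError

__all__ = [
    "MixtureModel",
    "CategoryThresholds",
    "CategoryFractions",
    "global_threshold",
    "kmeans_1d",
    "KMeansResult",
    "fit_gmm_em",
    "component_intersections",
    "categorize_intensities",
    "CATEGORIES",
]

CATEGORIES = ("strong", "moderate", "weak", "negative")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MixtureModel:
    """A 1-D Gaussian mixture over white pixel intensity.

    Components are stored sorted by ascending mean; on the white-intensity
    axis the lowest mean is the *strongest* staining component.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float | None = None
    n_iter: int | None = None
    converged: bool | None = None
    log_likelihood_history: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        if not (w.shape == mu.shape == sd.shape) or w.ndim != 1 or w.size == 0:
            raise ValidationError("weights, means and sds must be equal-length 1-D arrays")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights must sum to 1, got {w.sum()!r}")
        if np.any(w < 0):
            raise ValidationError("mixture weights must be non-negative")
        if np.any(sd <= 0):
            raise ValidationError("mixture SDs must be strictly positive")
        order = np.argsort(mu, kind="stable")
        object.__setattr__(self, "weights", w[order])
        object.__setattr__(self, "means", mu[order])
        object.__setattr__(self, "sds", sd[order])

    @property
    def k(self) -> int:
        return self.weights.size

    def pdf(self, x) -> np.ndarray:
        """Mixture density at ``x``."""
        return np.exp(self.logpdf(x))

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        logcomp = (
            np.log(np.maximum(self.weights, 1e-300))
            - np.log(self.sds)
            - 0.5 * (_LOG_2PI + z * z)
        )
        return logsumexp(logcomp, axis=-1)

    def component_density(self, x, s: int, weighted: bool = True) -> np.ndarray:
        """Density of component ``s`` (weight-scaled by default) at ``x``."""
        x = np.asarray(x, dtype=float)
        z = (x - self.means[s]) / self.sds[s]
        d = np.exp(-0.5 * z * z) / (self.sds[s] * np.sqrt(2.0 * np.pi))
        return self.weights[s] * d if weighted else d


@dataclass(frozen=True)
class CategoryThresholds:
    """Background cutoff t0 and category boundaries t1 < t2 on the 0-255 scale."""

    t0: float
    t1: float
    t2: float

    def __post_init__(self):
        if not (0 < self.t1 < self.t2 < self.t0 <= 255):
            raise ValidationError(
                f"thresholds must satisfy 0 < t1 < t2 < t0 <= 255, got "
                f"t0={self.t0}, t1={self.t1}, t2={self.t2}"
            )

    @classmethod
    def from_mixture(
        cls, model: MixtureModel, t0: float, weighted: bool = True
    ) -> "CategoryThresholds":
        t1, t2 = component_intersections(model, weighted=weighted)
        try:
            return cls(t0=float(t0), t1=t1, t2=t2)
        except ValidationError as exc:  # fit rejected with a diagnostic
            raise ValidationError(
                f"mixture fit yields unusable thresholds (t1={t1:.3f}, t2={t2:.3f}, "
                f"t0={t0}): {exc}"
            ) from exc

    def to_dict(self) -> dict:
        return {"t0": self.t0, "t1": self.t1, "t2": self.t2}


# ---------------------------------------------------------------------------
# Otsu background threshold
# ---------------------------------------------------------------------------

def global_threshold(histogram: Sequence[float], override: int | None = None) -> int:
    """Global histogram threshold maximizing between-class variance (Otsu).

    ``histogram`` holds counts per integer intensity (256 bins for 8-bit data).
    Returns the integer threshold ``t`` such that the low class is ``value <= t``;
    ties are broken toward the smallest threshold.  An explicit ``override``
    (e.g. a conventional background cutoff of 230) bypasses the computation.

    The argmax is computed in exact rational arithmetic so results are
    reproducible to the bin, even on histograms with exact variance ties.
    """
    if override is not None:
        return int(override)
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise ValidationError(f"histogram must be 1-D with >= 2 bins, got shape {h.shape}")
    if np.any(h < 0) or not np.all(np.isfinite(h)):
        raise ValidationError("histogram counts must be finite and non-negative")
    if h.sum() == 0:
        raise ValidationError("histogram is empty (total count is zero)")

    nonzero = np.flatnonzero(h)
    if nonzero.size == 1:
        warnings.warn(
            f"histogram has a single occupied bin ({nonzero[0]}); threshold is degenerate",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return int(nonzero[0])

    # Float pre-pass: between-class variance ∝ (s0*w1 - s1*w0)^2 / (w0*w1).
    w0f = np.cumsum(h)[:-1]
    s0f = np.cumsum(np.arange(h.size) * h)[:-1]
    w1f = h.sum() - w0f
    s1f = (np.arange(h.size) * h).sum() - s0f
    with np.errstate(invalid="ignore", divide="ignore"):
        valf = (s0f * w1f - s1f * w0f) ** 2 / (w0f * w1f)
    valf[(w0f == 0) | (w1f == 0)] = -np.inf
    vmax = valf.max()
    candidates = np.flatnonzero(valf >= vmax * (1.0 - 1e-9) - 1e-9)

    # Exact rational comparison among the near-tie candidates only.
    counts = [Fraction(int(c)) if c == int(c) else Fraction(c) for c in h.tolist()]
    total_w = sum(counts)
    total_s = sum(i * c for i, c in enumerate(counts))
    best_t, best_val = None, None
    for t in sorted(int(t) for t in candidates):
        w0 = sum(counts[: t + 1])
        s0 = sum(i * c for i, c in enumerate(counts[: t + 1]))
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        s1 = total_s - s0
        num = s0 * w1 - s1 * w0
        val = Fraction(num * num, w0 * w1)
        if best_val is None or val > best_val:
            best_t, best_val = t, val
    assert best_t is not None
    return best_t


# ---------------------------------------------------------------------------
# 1-D k-means (EM initialization)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMeansResult:
    centers: np.ndarray  # sorted ascending
    labels: np.ndarray
    inertia: float
    n_iter: int
    inertia_history: np.ndarray


def kmeans_1d(
    values: Sequence[float], k: int, seed: int | None = None, max_iter: int = 300
) -> KMeansResult:
    """Lloyd's algorithm on 1-D data.

    Default initialization uses the ``(2i+1)/(2k)`` quantiles of the data,
    which makes the run deterministic without a seed; passing ``seed`` instead
    draws the initial centers from distinct data values at random.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("k-means requires at least one value")
    distinct = np.unique(x)
    if distinct.size < k:
        raise ValidationError(
            f"k-means needs at least k={k} distinct values, got {distinct.size}"
        )
    if seed is None:
        centers = np.quantile(x, (2 * np.arange(k) + 1) / (2 * k))
        # quantile init can duplicate centers on highly discrete data
        if np.unique(centers).size < k:
            centers = distinct[np.linspace(0, distinct.size - 1, k).astype(int)]
    else:
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.choice(distinct, size=k, replace=False))

    labels = np.zeros(x.size, dtype=int)
    history = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = np.abs(x[:, None] - centers[None, :])
        labels = np.argmin(d, axis=1)
        history.append(float(np.sum((x - centers[labels]) ** 2)))
        new_centers = centers.copy()
        for j in range(k):
            sel = labels == j
            if np.any(sel):
                new_centers[j] = x[sel].mean()
        if np.array_equal(new_centers, centers):
            break
        centers = new_centers

    order = np.argsort(centers, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return KMeansResult(
        centers=centers[order],
        labels=relabel[labels],
        inertia=history[-1],
        n_iter=n_iter,
        inertia_history=np.asarray(history),
    )


# ---------------------------------------------------------------------------
# EM for the Gaussian mixture
# ---------------------------------------------------------------------------

def _em_init(data, k, init, seed):
    if isinstance(init, MixtureModel):
        if init.k != k:
            raise ValidationError(f"init model has k={init.k}, expected {k}")
        return init.weights.copy(), init.means.copy(), init.sds.copy()
    if init != "kmeans":
        raise ValidationError(f"unknown init {init!r}; use 'kmeans' or a MixtureModel")
    km = kmeans_1d(data, k, seed=seed)
    weights = np.bincount(km.labels, minlength=k).astype(float)
    means = km.centers.copy()
    sds = np.empty(k)
    for j in range(k):
        sel = km.labels == j
        sds[j] = data[sel].std() if np.any(sel) else data.std()
    weights = np.maximum(weights, 1.0)
    weights /= weights.sum()
    sds = np.maximum(sds, 0.5)
    return weights, means, sds


def fit_gmm_em(
    values: Sequence[float],
    k: int = 3,
    *,
    init: "str | MixtureModel" = "kmeans",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    sigma_floor: float = 0.5,
    weight_floor: float = 1e-4,
) -> MixtureModel:
    """Fit a k-component Gaussian mixture to 1-D intensities by EM.

    The fit runs on the value histogram — ``np.unique`` with counts — which is
    mathematically identical to per-observation EM for quantized data and much
    faster on megapixel images.  The E-step computes responsibilities in the
    log domain; the M-step floors SDs at ``sigma_floor`` (grey levels) to keep
    quantized data from collapsing a component onto a single bin.

    Raises
    ------
    ComponentCollapseError
        If a component weight drops below ``weight_floor`` twice (once after a
        re-initialization of the offending component).
    """
    x_all = np.asarray(values, dtype=float).ravel()
    if x_all.size < 10 * k:
        raise ValidationError(f"need at least {10 * k} values to fit k={k}, got {x_all.size}")
    if not np.all(np.isfinite(x_all)):
        raise ValidationError("values must be finite")
    x, counts = np.unique(x_all, return_counts=True)
    counts = counts.astype(float)
    n = counts.sum()

    weights, means, sds = _em_init(x_all, k, init, seed)
    sds = np.maximum(sds, sigma_floor)

    reinit_used = False
    ll_prev = -np.inf
    history: list[float] = []
    n_iter = 0
    converged = False
    rng = np.random.default_rng(seed)

    for n_iter in range(1, max_iter + 1):
        # E-step (log domain, histogram-weighted)
        z = (x[:, None] - means[None, :]) / sds[None, :]
        logcomp = (
            np.log(np.maximum(weights, 1e-300))[None, :]
            - np.log(sds)[None, :]
            - 0.5 * (_LOG_2PI + z * z)
        )
        logmix = logsumexp(logcomp, axis=1)
        ll = float(np.dot(counts, logmix))
        history.append(ll)
        resp = np.exp(logcomp - logmix[:, None])

        # M-step
        nk = (counts[:, None] * resp).sum(axis=0)
        if np.any(nk / n < weight_floor):
            bad = int(np.argmin(nk))
            if reinit_used:
                raise ComponentCollapseError(
                    f"component {bad} collapsed (weight {nk[bad] / n:.2e} < "
                    f"{weight_floor}) after re-initialization; the data likely "
                    f"support fewer than k={k} components"
                )
            reinit_used = True
            means[bad] = np.quantile(x_all, rng.uniform(0.05, 0.95))
            sds[bad] = max(x_all.std(), sigma_floor)
            weights = np.full(k, 1.0 / k)
            ll_prev = -np.inf
            continue
        weights = nk / n
        means = (counts[:, None] * resp * x[:, None]).sum(axis=0) / nk
        var = (counts[:, None] * resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sigma_floor)

        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll

    return MixtureModel(
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=history[-1],
        n_iter=n_iter,
        converged=converged,
        log_likelihood_history=np.asarray(history),
    )


# ---------------------------------------------------------------------------
# Intersection thresholds
# ---------------------------------------------------------------------------

def _pair_intersection(w1, m1, s1, w2, m2, s2) -> float:
    """Intersection of two weighted Gaussian densities strictly between their means."""
    if m1 >= m2:
        raise ValidationError(f"component means must be strictly ascending ({m1} >= {m2})")
    L = np.log((w2 * s1) / (w1 * s2))
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = -2.0 * (m2 / s2**2 - m1 / s1**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 - 2.0 * L

    roots: list[float] = []
    if abs(a) < 1e-14:  # equal SDs -> linear equation
        if b != 0:
            roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if m1 < r < m2]
    if inside:
        return float(min(inside))

    # Extreme weight imbalance can push both density crossings outside
    # (m1, m2); fall back to the responsibility-equality point, which always
    # crosses between the means.
    def g(xv):
        z1 = (xv - m1) / s1
        z2 = (xv - m2) / s2
        return (np.log(w1) - np.log(s1) - 0.5 * z1 * z1) - (
            np.log(w2) - np.log(s2) - 0.5 * z2 * z2
        )

    lo, hi = m1 + 1e-9, m2 - 1e-9
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise ValidationError(
            f"no density or responsibility crossing between means {m1} and {m2}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if glo * g(mid) <= 0:
            hi = mid
        else:
            lo, glo = mid, g(mid)
    return float(0.5 * (lo + hi))


def component_intersections(model: MixtureModel, *, weighted: bool = True) -> tuple[float, ...]:
    """Category thresholds at the intersections of adjacent mixture components.

    For each adjacent pair of components (sorted by mean), solves
    ``pi_s N(x; mu_s, sd_s) = pi_{s+1} N(x; mu_{s+1}, sd_{s+1})`` — a quadratic
    in x — and returns the root strictly between the two means.  With
    ``weighted=False`` the component weights are ignored (plain density
    intersection).  For the default k = 3 this returns ``(t1, t2)`` with
    ``t1 < t2`` guaranteed.
    """
    mu = model.means
    if np.any(np.diff(mu) <= 0):
        raise ValidationError(f"degenerate mixture: means not strictly ascending ({mu})")
    w = model.weights if weighted else np.full(model.k, 1.0 / model.k)
    out = tuple(
        _pair_intersection(w[s], mu[s], model.sds[s], w[s + 1], mu[s + 1], model.sds[s + 1])
        for s in range(model.k - 1)
    )
    return out


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryFractions:
    """Fractions of weak/moderate/strong values over the chosen denominator."""

    weak: float
    moderate: float
    strong: float
    denominator: Literal["positive", "all"]
    n_positive: int
    n_total: int
    all_negative: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.weak, self.moderate, self.strong)


def categorize_intensities(
    values: Sequence[float],
    thresholds: CategoryThresholds,
    denominator: Literal["positive", "all"] = "positive",
) -> tuple[np.ndarray, CategoryFractions]:
    """Assign each white-intensity value a staining category and compute fractions.

    Boundary values go to the stronger side (``value <= t1`` is strong, etc.).
    Fractions are over positive values by default; with ``denominator="all"``
    the negative remainder is implicit (fractions then sum to the positive
    share, not to 1).  If no value is positive, fractions are zero and
    ``all_negative`` is set.
    """
    v = np.asarray(values, dtype=float)
    cats = np.where(
        v <= thresholds.t1,
        "strong",
        np.where(v <= thresholds.t2, "moderate", np.where(v <= thresholds.t0, "weak", "negative")),
    )
    n_total = v.size
    n_strong = int(np.sum(cats == "strong"))
    n_moderate = int(np.sum(cats == "moderate"))
    n_weak = int(np.sum(cats == "weak"))
    n_pos = n_strong + n_moderate + n_weak
    denom = n_pos if denominator == "positive" else n_total
    if denom == 0 or (denominator == "positive" and n_pos == 0):
        frac = CategoryFractions(0.0, 0.0, 0.0, denominator, n_pos, n_total, all_negative=True)
    else:
        frac = CategoryFractions(
            weak=n_weak / denom,
            moderate=n_moderate / denom,
            strong=n_strong / denom,
            denominator=denominator,
            n_positive=n_pos,
            n_total=n_total,
        )
    return cats, frac
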