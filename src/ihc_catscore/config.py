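"""Run configuration shared by the CLI commands.

The fully resolved configuration is echoed into every output for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import yaml

from .errors import ValidationError
from .stains import StainVectors


@dataclass
class RunConfig:
    """Validated settings for a pipeline run."""

    stain_vectors: StainVectors = field(default_factory=StainVectors.hdab)
    #: "auto" (Otsu) or a fixed integer cutoff such as 230.
    t0: "Literal['auto'] | int" = "auto"
    k: int = 3
    em_tol: float = 1e-6
    em_max_iter: int = 500
    em_seed: int | None = None
    #: denominator for category fractions: positive cells or all cells
    denominator: Literal["positive", "all"] = "positive"
    #: region mean-intensity mode
    region_mode: Literal["positive-pixels", "all-pixels"] = "positive-pixels"
    min_area: int = 20
    weighted_intersections: bool = True

    def __post_init__(self):
        if self.t0 != "auto":
            self.t0 = int(self.t0)
            if not (0 < self.t0 <= 255):
                raise ValidationError(f"t0 must be in (0, 255], got {self.t0}")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ValidationError("invalid EM settings")
        if self.denominator not in ("positive", "all"):
            raise ValidationError(f"unknown denominator {self.denominator!r}")
        if self.region_mode not in ("positive-pixels", "all-pixels"):
            raise ValidationError(f"unknown region mode {self.region_mode!r}")
        if self.min_area < 0:
            raise ValidationError("min_area must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stain_vectors" in data:
            data["stain_vectors"] = StainVectors.from_mapping(data["stain_vectors"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stain_vectors"] = self.stain_vectors.to_mapping()
        return d
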