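"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class PlacementError(RuntimeError):
    """Synthetic nuclei could not all be placed in the requested field."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} non-overlapping nuclei; "
            "enlarge the image or reduce the cell count / radius range"
        )


class ComponentCollapseError(RuntimeError):
    """An EM mixture component collapsed (weight below floor) even after re-initialization."""


class DegenerateDataWarning(UserWarning):
    """The input is degenerate for the requested computation (e.g. single-valued histogram)."""
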