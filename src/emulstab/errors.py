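"""Exception hierarchy for emulstab.

All user-input problems derive from :class:`InputError` (a ``ValueError``),
so callers can catch one type at the CLI boundary.
"""


class InputError(ValueError):
    """Invalid user-supplied value (out of range, wrong sign, empty input)."""


class PlacementError(RuntimeError):
    """A synthetic droplet could not be placed without overlap.

    Carries the index of the offending droplet in ``droplet_index``.
    """

    def __init__(self, droplet_index: int, retries: int):
        self.droplet_index = droplet_index
        self.retries = retries
        super().__init__(
            f"could not place droplet {droplet_index} without overlap "
            f"after {retries} retries; reduce density or set allow_overlap=True"
        )


class SimulationDomainError(ValueError):
    """A simulated linear predictor left the domain of the inverse transform."""


class AliasingError(ValueError):
    """Model matrix is rank deficient; some terms are aliased."""

    def __init__(self, aliased_terms):
        self.aliased_terms = list(aliased_terms)
        super().__init__(
            "design matrix is rank deficient; aliased terms: "
            + ", ".join(map(str, self.aliased_terms))
        )


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; ``diagnostics`` holds details."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class SchemaError(ValueError):
    """A table file does not match its declared schema."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {detail}")
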