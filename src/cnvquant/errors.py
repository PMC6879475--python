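"""Exception hierarchy used across the pipeline.

Every stage fails fast with a stage-specific error so that orchestration
code can distinguish unusable inputs (degenerate images, saturated
artefacts, failed registrations) from programming errors.
"""


class CnvQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(CnvQuantError):
    """An input violates a documented invariant."""


class SchemaError(ValidationError):
    """A manifest or table is missing required columns."""


class DegenerateImageError(ValidationError):
    """An image carries no usable signal (zero variance)."""


class ArtefactSaturationError(CnvQuantError):
    """Too many rows flagged as motion artefacts; frame deemed unusable."""

    def __init__(self, n_flagged: int, n_rows: int):
        self.n_flagged = n_flagged
        self.n_rows = n_rows
        super().__init__(
            f"{n_flagged}/{n_rows} rows flagged as motion artefacts "
            f"(> 30% of the frame); image deemed unusable"
        )


class RegistrationFailure(CnvQuantError):
    """Pairwise registration did not reach the acceptance score floor."""

    def __init__(self, score: float, floor: float):
        self.score = score
        self.floor = floor
        super().__init__(
            f"registration score {score:.3f} below acceptance floor {floor:.3f}"
        )


class SimulationError(CnvQuantError):
    """The vascular growth simulation could not satisfy its target."""


class SampleSizeError(ValidationError):
    """Too few observations for the requested statistic."""


class NoInformationError(ValidationError):
    """A paired test received data carrying no information (all ties)."""
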