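"""Exception hierarchy shared across the package."""


class PpisurfError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PpisurfError):
    """A structure file could not be parsed in the requested format."""


class DegenerateChainError(PpisurfError):
    """A chain retained too few atoms to define a surface."""

    def __init__(self, chain_id: str, n_atoms: int, minimum: int):
        self.chain_id = chain_id
        self.n_atoms = n_atoms
        super().__init__(
            f"chain {chain_id!r} retained {n_atoms} atoms (< {minimum} required)"
        )


class SamplingFailureError(PpisurfError):
    """Level-set descent failed for the majority of seed points."""

    def __init__(self, message: str, diagnostics: dict):
        self.diagnostics = diagnostics
        super().__init__(message)


class DegenerateGeometryError(PpisurfError):
    """Point configuration admits no 3-D convex hull (e.g. coplanar)."""


class ParameterError(PpisurfError, ValueError):
    """An operation parameter is outside its valid range."""


class ConfigurationError(PpisurfError):
    """Inconsistent model/run configuration flags or widths."""


class ShapeError(PpisurfError, ValueError):
    """An array argument has the wrong width or shape."""


class ProviderUnavailableError(PpisurfError):
    """A requested embedding provider cannot run in this installation."""


class ValidationError(PpisurfError, ValueError):
    """An input record violates a documented invariant."""


class SamplingExhaustedError(PpisurfError):
    """Negative-pair sampling cannot find enough non-excluded pairs."""


class TrainingSetupError(PpisurfError):
    """The training set cannot support optimisation (e.g. single class)."""
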