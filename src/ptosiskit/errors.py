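"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: configuration/validation problems exit
with 2, runtime failures with 3.
"""


class PtosisKitError(Exception):
    """Base class for all toolkit errors."""


class InvalidAnnotationError(PtosisKitError):
    """An eye annotation violates its geometric invariants."""


class MeasurementError(PtosisKitError):
    """A measurement is undefined for the given annotation."""


class ConfigurationError(PtosisKitError):
    """A parameter or configuration value is out of its valid range."""


class EvaluationError(PtosisKitError):
    """A symmetry evaluation cannot be computed (e.g. all angles missing)."""


class BackendError(PtosisKitError):
    """A generative backend violated its contract."""


class BackendNotInstalledError(BackendError):
    """The requested external engine is unavailable in this environment."""


class GuidanceError(PtosisKitError):
    """Guided sampling produced a non-finite gradient."""
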