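"""Exception hierarchy."""


class SVContextError(Exception):
    """Base class for package errors."""


class WindowRejected(SVContextError):
    """Window overlaps a chromosome end or contains non-ACGT bases."""


class SamplingError(SVContextError):
    """Could not place the requested windows/events after bounded retries."""


class PlacementError(SamplingError):
    """Simulator ran out of non-overlapping space for events."""


class ConfigurationError(SVContextError):
    """Invalid configuration value or unknown registry key."""


class DependencyError(SVContextError):
    """A pipeline stage was run before the artifact it needs exists."""
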