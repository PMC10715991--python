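"""Exception hierarchy.

All package errors derive from :class:`NirstabError` so callers (and the CLI)
can map failure classes to exit codes: config errors (2), data validation
errors (3), numerical failures (4).
"""


class NirstabError(Exception):
    """Base class for all nirstab errors."""


class ConfigError(NirstabError):
    """Invalid configuration value (bad window size, n_bins < 2, ...)."""


class ValidationError(NirstabError):
    """Data violates an invariant (duplicate ids, grid mismatch, bad pairing)."""


class FormatError(ValidationError):
    """A file could not be parsed as the expected dialect; message locates the defect."""


class AlignmentError(ValidationError):
    """Spectrum sets on incompatible wavenumber grids."""


class NumericalError(NirstabError):
    """Degenerate numerical situation (singular covariance in classical mode, zero-variance MSC reference)."""
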