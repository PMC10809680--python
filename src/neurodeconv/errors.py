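"""Exception hierarchy shared across the package.

All errors derive from :class:`NeurodeconvError` so callers can catch the
package's failures with a single except clause; each subclass marks the
contract that was violated (value domain, file format, parameters, ...).
"""


class NeurodeconvError(Exception):
    """Base class for all package errors."""


class BetaDomainError(NeurodeconvError, ValueError):
    """A methylation value fell outside the closed interval [0, 1]."""


class FormatError(NeurodeconvError, ValueError):
    """A file or table violates the expected layout (duplicate ids, bad header)."""


class ParameterError(NeurodeconvError, ValueError):
    """An argument combination is infeasible (e.g. too few sites for planting)."""


class ConfigError(NeurodeconvError, ValueError):
    """A configuration references unknown labels or is internally inconsistent."""


class SelectionError(NeurodeconvError, RuntimeError):
    """Site selection found no usable cell-specific sites for a fraction."""


class ApplicabilityError(NeurodeconvError, ValueError):
    """A method was requested outside its domain (e.g. IDOL with K <= 2)."""


class CoverageError(NeurodeconvError, RuntimeError):
    """Too few model sites are present in a bulk sample to deconvolve it."""


class InfeasibilityError(NeurodeconvError, ValueError):
    """The data cannot support the requested operation (e.g. 1 replicate)."""
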