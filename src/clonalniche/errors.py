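"""Exception hierarchy with stable exit-code classes for the CLI.

Exit codes: configuration errors (bad column maps, unknown config keys) are 2,
validation errors (data violating a stated invariant) are 3, domain errors
(operations undefined on the given input) are 4, and I/O failures are 5.
"""

from __future__ import annotations


class ClonalNicheError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ClonalNicheError):
    """A configuration problem: missing role in a column map, unknown parameter key."""

    exit_code = 2


class ValidationError(ClonalNicheError):
    """Input data violates a stated invariant (duplicate ids, bad coordinates...)."""

    exit_code = 3


class DomainError(ClonalNicheError):
    """The requested operation is undefined on this input (e.g. empty repertoire)."""

    exit_code = 4


class DegenerateGeometryError(DomainError):
    """Geometry too degenerate for the requested method (e.g. collinear hull input)."""


class GenerationError(DomainError):
    """A simulator could not satisfy its constraints (e.g. niche separation)."""
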