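"""Exception hierarchy shared across the package.

All errors derive from :class:`IfaceError` so callers can catch package
failures with a single except clause; the subclasses mirror the distinct
failure modes of the pipeline stages (parsing, congruence between poses or
frames, chain partitioning, fitting).
"""


class IfaceError(Exception):
    """Base class for all package-specific errors."""


class InputError(IfaceError, ValueError):
    """Invalid or empty user input (missing file, empty structure, bad value)."""


class ParseError(IfaceError, ValueError):
    """Malformed file content; the message names the offending line."""


class CongruenceError(IfaceError, ValueError):
    """Objects that must share an atom/residue key space do not."""


class PartitionError(IfaceError, ValueError):
    """Receptor/ligand chain sets overlap or have the wrong cardinality."""


class SymmetryMapError(IfaceError, ValueError):
    """A residue map that must be a bijection is not, or misses a key."""


class MappingError(IfaceError, ValueError):
    """Structure sequence and alignment row disagree at an aligned position."""


class FitError(IfaceError, RuntimeError):
    """Nonlinear fit failed to converge from every start."""


class GenerationError(IfaceError, RuntimeError):
    """A synthetic-data generator could not satisfy its planted constraints."""


class DataQualityWarning(UserWarning):
    """Data violate a soft expectation (e.g. a titration that is not monotone)."""
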