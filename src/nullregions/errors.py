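"""Exception hierarchy.

Specification errors mean the *test specification* is wrong (bad null-region
parameters, impossible confidence level); data errors mean the supplied data
cannot support the requested computation (groups too small, degenerate
correlation).  The CLI maps the two to distinct diagnostics.
"""


class NullRegionsError(Exception):
    """Base class for all package errors."""


class SpecificationError(NullRegionsError, ValueError):
    """The test specification (region parameters, level, method) is invalid."""


class DataError(NullRegionsError, ValueError):
    """The supplied data cannot support the requested computation."""


class ConsistencyError(NullRegionsError, RuntimeError):
    """Internal geometric consistency violated (e.g. complementary tests both
    significant on the same confidence interval)."""


class UnreachablePowerError(NullRegionsError, RuntimeError):
    """The target power cannot be reached by any sample size up to the search
    cap (possible for narrow central-gap geometries)."""
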