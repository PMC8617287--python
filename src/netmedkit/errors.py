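"""Exception hierarchy.

Every failure mode surfaced by the library is a :class:`NetmedkitError`
subclass so that callers (and the CLI) can catch one base type and still
discriminate on the specific condition.
"""


class NetmedkitError(Exception):
    """Base class for all errors raised by this package."""


class GraphMLParseError(NetmedkitError):
    """Malformed XML in a GraphML input; message names the offending line."""


class SchemaError(NetmedkitError):
    """A node or edge violates the heterogeneous-network schema."""


class ReferentialError(NetmedkitError):
    """An edge references node ids that are absent from the node table."""


class UnknownNodeError(NetmedkitError):
    """A lookup referenced a node id that is not in the network."""


class SeedError(NetmedkitError):
    """Seed set empty, unmapped, or otherwise unusable for an algorithm."""


class ConnectivityError(NetmedkitError):
    """Terminals/seeds span multiple components where one is required."""

    def __init__(self, message, unreachable=()):
        super().__init__(message)
        self.unreachable = tuple(unreachable)


class IsolationError(NetmedkitError):
    """No seed has any interaction edge in the relevant layer."""


class ParameterError(NetmedkitError):
    """A numeric parameter is outside its documented domain."""


class SamplingError(NetmedkitError):
    """A random-sampling routine could not satisfy its constraints."""


class InputError(NetmedkitError):
    """User-supplied list or table violates a precondition (e.g. duplicates)."""
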