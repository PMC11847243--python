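"""Exception hierarchy for szind."""


class SzindError(Exception):
    """Base class for all szind-specific errors."""


class GraphFormatError(SzindError, ValueError):
    """Malformed graph input (edge-list text, SMILES string, graph spec)."""


class DisconnectedGraphError(SzindError, ValueError):
    """A distance-based index was requested on a disconnected graph."""


class FixtureIntegrityError(SzindError, RuntimeError):
    """A packaged data fixture failed its checksum or matching invariant."""
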