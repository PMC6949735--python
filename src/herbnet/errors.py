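"""Exception hierarchy shared across the package."""


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(HerbnetError):
    """A required column is missing or a table violates its schema."""


class TableParseError(HerbnetError):
    """A cell could not be parsed; the message carries the row number."""


class ConfigError(HerbnetError):
    """An invalid simulation or pipeline configuration."""


class NetworkBuildError(HerbnetError):
    """An edge list cannot be assembled into a valid bipartite graph."""


class EnrichmentError(HerbnetError):
    """Invalid enrichment inputs (empty background, non-functional module map...)."""
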