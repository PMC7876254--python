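"""Exception hierarchy shared across gazediag modules."""


class GazeDiagError(Exception):
    """Base class for all gazediag errors."""


class ConfigError(GazeDiagError):
    """A configuration file or parameter set is malformed or inconsistent."""


class FormatError(GazeDiagError):
    """A tabular input file violates the documented column layout."""


class ValidationError(GazeDiagError):
    """Data parsed correctly but violates an invariant (bounds, order, ids)."""


class FitError(GazeDiagError):
    """A model fit could not be carried out on the given data."""
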