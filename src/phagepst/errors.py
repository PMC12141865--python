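"""Exception hierarchy shared by all phagepst modules."""


class PstError(Exception):
    """Base class for all phagepst errors."""


class FormatError(PstError):
    """A file or table does not conform to the expected schema."""


class DataError(PstError):
    """Structurally valid input with inconsistent data (e.g. non-monotone times)."""


class ValidationError(PstError):
    """An input violates a domain invariant."""


class RangeError(PstError):
    """A requested window or index lies outside the sampled range."""


class DegenerateControlError(PstError):
    """An uninfected control curve integrates to zero (empty/failed well)."""


class GenerationError(PstError):
    """A synthetic-data request cannot be satisfied (e.g. infeasible planting)."""
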