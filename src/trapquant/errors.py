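"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`TrapQuantError`
so callers (and the CLI) can distinguish tool errors from programming bugs.
"""


class TrapQuantError(Exception):
    """Base class for all trapquant errors."""


class ImageReadError(TrapQuantError, IOError):
    """A file could not be read as an image; message names the path."""


class ConfigurationError(TrapQuantError):
    """Invalid configuration or channel/role bookkeeping."""


class ConfigFileError(ConfigurationError):
    """A configuration file could not be parsed or validated."""


class SchemaVersionError(ConfigFileError):
    """Configuration file schema version does not match this package."""


class LookupFieldError(TrapQuantError, KeyError):
    """An unknown field-of-view id was requested."""


class SampleSizeError(TrapQuantError, ValueError):
    """Requested annotation sample exceeds the object pool."""


class MissingPredictionError(TrapQuantError, KeyError):
    """An annotated object has no prediction; message names the object."""


class FittingError(TrapQuantError, ValueError):
    """Automatic threshold fitting is impossible (e.g. one class absent)."""


class EmbeddingSizeError(TrapQuantError, ValueError):
    """Too few objects for a 2-D embedding."""


class GeometryError(TrapQuantError, ValueError):
    """Invalid polygon supplied for cluster selection."""


class PlacementError(TrapQuantError, RuntimeError):
    """Synthetic objects could not be placed without overlap."""
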