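"""Exception hierarchy.

All catfield errors derive from :class:`CatfieldError` so callers can
catch the package's failures with one clause; the subclasses distinguish
bad files, bad geometry and bad usage.
"""


class CatfieldError(Exception):
    """Base class for all catfield errors."""


class FormatError(CatfieldError, ValueError):
    """A file does not follow its declared format (names the line/row)."""


class UsageError(CatfieldError, ValueError):
    """An operation was called with arguments that make no sense."""


class ConfigurationError(CatfieldError, ValueError):
    """Missing configuration data, e.g. an element without a vdW radius."""


class ProximityError(CatfieldError, ValueError):
    """An evaluation point lies inside the multipole-expansion guard radius."""


class DegenerateGeometryError(CatfieldError, ValueError):
    """Too few or collinear atoms for a unique rigid-body alignment."""


class SiteGeometryError(CatfieldError, ValueError):
    """A substitution site does not look like a terminal hydrogen."""
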