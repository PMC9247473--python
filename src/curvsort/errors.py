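"""Exception hierarchy for curvsort."""


class CurvsortError(Exception):
    """Base class for all curvsort errors."""


class ValidationError(CurvsortError, ValueError):
    """Invalid input values (compositions, fractions, parameters)."""


class ParseError(CurvsortError, ValueError):
    """Malformed coordinate file."""


class GeometryError(CurvsortError, ValueError):
    """Unsupported or degenerate geometry (non-orthorhombic box,
    self-intersecting leaflet offset, cutoff larger than the minimum-image
    limit, negative strain)."""


class DegenerateMembraneError(CurvsortError, ValueError):
    """Leaflet assignment produced an empty leaflet."""


class FitError(CurvsortError, RuntimeError):
    """Spline fit could not be performed (too few points, solver failure)."""


class ModelInconsistencyError(CurvsortError, ValueError):
    """Sorting model assigns zero probability to every species somewhere."""


class ConfigError(CurvsortError, ValueError):
    """Invalid or unknown configuration keys/values."""


class NotApplicableError(CurvsortError, ValueError):
    """Descriptor undefined for the species (e.g. splay angle of a
    single-tail or no-tail species)."""
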