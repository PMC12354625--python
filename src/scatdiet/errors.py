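"""Exception hierarchy for scatdiet."""


class ScatDietError(Exception):
    """Base class for all scatdiet errors."""


class ConfigError(ScatDietError):
    """Invalid configuration (bad parameter value, unknown taxon, missing path)."""


class HitParseError(ScatDietError):
    """Malformed alignment hit table row."""


class ConsistencyError(ScatDietError):
    """Cross-stage inconsistency, e.g. a query with no cluster record."""
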