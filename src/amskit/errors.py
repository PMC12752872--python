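"""Exception hierarchy shared across the toolkit."""


class AmskitError(Exception):
    """Base class for all toolkit errors."""


class UnitError(AmskitError, ValueError):
    """Dose unit is not convertible to the drug's reference unit."""


class FixtureError(AmskitError, ValueError):
    """Packaged or user-supplied formulary/registry file is malformed."""


class DrugLookupError(AmskitError, KeyError):
    """A drug_id (or combination component) is not in the formulary."""


class RecordParseError(AmskitError, ValueError):
    """A record file could not be parsed; message names record and field."""


class DomainError(AmskitError, ValueError):
    """An argument is outside its documented domain."""


class SchedulingError(AmskitError, ValueError):
    """Appointment arithmetic is impossible (e.g. no injections on file)."""


class ConfigError(AmskitError, ValueError):
    """A generator or schedule configuration violates its invariants."""
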