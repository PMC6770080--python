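"""Exception hierarchy for the two-sample MR pipeline.

Configuration problems (bad column maps, malformed config files) exit a CLI
run with code 1; data problems (empty instrument sets, degenerate inputs)
exit with code 2.
"""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """A config file, column map or parameter is malformed or missing."""


class InputError(TsmrError):
    """An input file is unreadable, empty, or structurally invalid."""


class EmptyInstrumentError(TsmrError):
    """No variant survives instrument selection; MR cannot proceed."""


class InsufficientInstrumentsError(TsmrError):
    """An operation needs more instruments than were supplied (e.g. k >= 2)."""


class DegenerateInstrumentError(TsmrError):
    """A variant-exposure effect of exactly zero makes the Wald ratio undefined."""


class ScaleMismatchError(TsmrError):
    """A transform was requested on the wrong outcome scale."""
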