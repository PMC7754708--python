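"""Exception types shared across the package."""


class PlacestimError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PlacestimError):
    """A session container is missing a required group or dataset."""


class SessionValidationError(PlacestimError):
    """A loaded or constructed session violates a structural invariant."""


class ConfigError(PlacestimError):
    """An invalid parameter combination was supplied."""


class ProtocolError(PlacestimError):
    """A stimulation protocol is inconsistent with the session it targets."""


class AlignmentError(PlacestimError):
    """Behavior and imaging clocks disagree by more than one frame."""


class AnalysisError(PlacestimError):
    """An analysis precondition is not met (degenerate input, too few trials...)."""
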