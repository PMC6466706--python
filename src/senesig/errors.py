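"""Exception hierarchy for senesig."""


class SenesigError(Exception):
    """Base class for all senesig errors."""


class ConfigurationError(SenesigError, ValueError):
    """A configuration value is outside its documented domain."""


class ValidationError(SenesigError, ValueError):
    """An input object violates a structural invariant."""


class MissingTagError(SenesigError, KeyError):
    """Query tags are absent from an instance ranking."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            f"{len(self.missing)} query tag(s) absent from instance ranking: "
            f"{', '.join(self.missing[:10])}"
            + ("..." if len(self.missing) > 10 else "")
        )


class MissingAnnotationError(SenesigError, KeyError):
    """Probes or genes lack an annotation entry."""

    def __init__(self, missing, kind="probe"):
        self.missing = sorted(missing)
        super().__init__(
            f"{len(self.missing)} {kind}(s) without annotation: "
            f"{', '.join(self.missing[:10])}"
            + ("..." if len(self.missing) > 10 else "")
        )
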