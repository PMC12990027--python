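"""Exception hierarchy shared across the package."""


class JawMotionError(Exception):
    """Base class for all package-specific failures."""


class StlFormatError(JawMotionError):
    """Raised when an STL payload cannot be parsed or is inconsistent."""


class RegistrationError(JawMotionError):
    """Raised when a rigid pose cannot be estimated from the given inputs."""


class MotionFormatError(JawMotionError):
    """Raised when a motion document is malformed or violates its invariants."""
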