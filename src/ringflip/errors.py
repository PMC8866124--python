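"""Package exception hierarchy."""


class RingflipError(Exception):
    """Base class for all errors raised by this package."""


class UnknownNucleusError(RingflipError, ValueError):
    """A nucleus label outside the supported set (15N, 1HN/1H, 13C)."""


class ScheduleError(RingflipError, ValueError):
    """A CPMG or spin-lock schedule violates its invariants."""


class DataError(RingflipError, ValueError):
    """Malformed or inconsistent input data."""


class FitError(RingflipError, RuntimeError):
    """Optimisation failed or produced an unusable result."""


class StructureError(RingflipError, ValueError):
    """Missing atoms/residues or degenerate coordinate selections."""
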