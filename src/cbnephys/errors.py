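"""Exception hierarchy for analysis failures.

All analysis errors derive from :class:`CbnEphysError` so pipeline code can
distinguish data problems from programming errors.
"""


class CbnEphysError(Exception):
    """Base class for all cbnephys analysis errors."""


class NonConvergence(CbnEphysError):
    """Curve fit failed after all optimizer restarts."""


class WindowTooShort(CbnEphysError):
    """Analysis window contains too few usable samples."""


class NoDecay(CbnEphysError):
    """Signal does not decrease over the requested decay window."""


class StimulusOutsideTrace(CbnEphysError):
    """A stimulus time (or its measurement point) falls outside the trace."""


class UnevokedTrace(CbnEphysError):
    """First phasic amplitude does not exceed the noise floor."""


class TooFewStimuli(CbnEphysError):
    """Train metric requested with fewer stimuli than it requires."""


class EmptyGroup(CbnEphysError):
    """A group comparison received an empty group."""


class ProtocolMismatch(CbnEphysError):
    """Ramp traces were recorded under different protocols."""


class NotCurrentClamp(CbnEphysError):
    """Spike analysis on a trace that is not a current-clamp recording."""


class TooFewSpikes(CbnEphysError):
    """Spike-shape metric requested with too few spikes."""


class ZeroPreRate(CbnEphysError):
    """Rebound percent change undefined when the pre-stimulus rate is 0."""


class InsufficientWindow(CbnEphysError):
    """Pre/post analysis windows extend beyond the recorded trace."""


class UnpairedInput(CbnEphysError):
    """Paired comparison received unmatched cell identifiers."""


class InvalidN(CbnEphysError):
    """Group size too small for the requested statistic."""


class MissingMetric(CbnEphysError):
    """Requested metric absent from the cohort table."""


class NonFiniteInput(CbnEphysError):
    """Inputs contain NaN or infinite values."""
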