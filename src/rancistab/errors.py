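"""Exception hierarchy.

Everything raised on bad user input or undetectable signals derives from
:class:`RancistabError`; the CLI maps these to exit code 1 and anything
else to exit code 2.
"""


class RancistabError(Exception):
    """Base class for all package errors."""


# --- trace / induction ------------------------------------------------------

class TraceError(RancistabError):
    """Invalid conductivity trace."""


class TooFewPoints(TraceError):
    """Trace has fewer samples than the detector needs."""


class NonMonotoneTime(TraceError):
    """Time axis is not strictly increasing."""


class NoInductionDetected(RancistabError):
    """No sharp conductivity rise distinguishable from baseline drift."""


# --- kinetics ---------------------------------------------------------------

class EmptyCell(RancistabError):
    """A requested (temperature, airflow) cell has no replicates."""


class DegenerateTemperatures(RancistabError):
    """Fewer than two distinct temperatures in a regression input."""


class NonPositiveOSI(RancistabError):
    """OSI values must be strictly positive (log model)."""


class NonUniformSpacing(RancistabError):
    """Q10 requires an exact 10 degree C temperature chain."""


class FewerThanTwoTemperatures(RancistabError):
    """Q10 needs at least one adjacent temperature pair."""


# --- panel statistics -------------------------------------------------------

class ConstantSeries(RancistabError):
    """Pearson correlation undefined for a zero-variance series."""


class LengthMismatch(RancistabError):
    """Paired series have different lengths."""


class TooFewPairs(RancistabError):
    """Fewer than three complete pairs for a correlation."""


class KeyMismatch(RancistabError):
    """OSI values and quality panels do not align on sample keys."""


class UnbalancedBelowMinimum(RancistabError):
    """ANOVA cell with fewer than two replicates."""


# --- I/O --------------------------------------------------------------------

class MissingColumn(RancistabError):
    """Required column absent from an input file."""


class NonNumericValue(RancistabError):
    """Numeric column contains an unparseable value."""


class UnsortedTime(RancistabError):
    """Trace file time column not strictly increasing."""


class InvalidConfig(RancistabError):
    """Simulation or run configuration violates an invariant."""
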