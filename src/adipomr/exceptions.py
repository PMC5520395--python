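"""Exception hierarchy for the adipomr package."""


class AdipoMRError(Exception):
    """Base class for all package-specific errors."""


class SummaryFormatError(AdipoMRError):
    """A summary-statistic file is malformed (e.g. a required column is missing)."""


class RecordValidationError(AdipoMRError):
    """A single row of a summary-statistic table failed validation.

    Carries the 1-based file line number when raised by a reader.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateInstrumentError(AdipoMRError):
    """An instrument has a zero exposure effect, so its Wald ratio is undefined."""


class InsufficientInstrumentsError(AdipoMRError):
    """Too few instruments for the requested estimator (MR-Egger needs >= 3)."""


class CollinearInstrumentsError(AdipoMRError):
    """All exposure effects are identical after orientation; the Egger fit is singular."""


class EstimationInputError(AdipoMRError):
    """Inconsistent estimator input (mixed cohorts/scales, mismatched pair sets, ...)."""


class SimulationError(AdipoMRError):
    """The synthetic-data generator could not satisfy its constraints."""
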