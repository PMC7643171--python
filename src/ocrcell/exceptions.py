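"""Exception hierarchy for the pipeline."""


class OcrCellError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OcrCellError):
    """Invalid simulation or analysis configuration."""


class InputError(OcrCellError):
    """Inputs violate a documented precondition."""


class ParseError(OcrCellError):
    """Malformed record in an input file; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedMetricError(OcrCellError):
    """A QC metric is undefined for the given input (e.g. zero reads)."""


class NormalizationError(OcrCellError):
    """Normalization cannot be computed (e.g. all-zero promoter counts)."""


class PipelineError(OcrCellError):
    """A pipeline stage produced a degenerate result (e.g. all OCRs filtered)."""
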