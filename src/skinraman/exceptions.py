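"""Exception types shared across the pipeline."""


class SkinRamanError(Exception):
    """Base class for package-specific errors."""


class ConfigError(SkinRamanError, ValueError):
    """Invalid configuration or arguments."""


class FormatError(SkinRamanError, ValueError):
    """Malformed input file (missing columns, wrong layout)."""


class DegenerateInputError(SkinRamanError, ValueError):
    """Input that is numerically degenerate (e.g. a constant spectrum
    cannot be SNV-normalized)."""


class DegenerateFitError(SkinRamanError, RuntimeError):
    """Model fit is undefined (e.g. zero covariance between spectra and
    class response)."""
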