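"""Exception hierarchy for the pull-down analysis pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """An input file violates its documented format contract."""


class DuplicateSpectrumError(FormatError):
    """Two PSM rows share the same (sample_id, spectrum_id)."""


class ConfigError(PipelineError):
    """A configuration value is out of range or inconsistent."""


class NormalizationError(PipelineError):
    """Spectral-count normalisation is undefined (all-zero sample)."""
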