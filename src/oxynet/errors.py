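"""Exception hierarchy shared across the pipeline."""


class OxynetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OxynetError):
    """An invalid configuration value; the message names the offending field."""


class DataError(OxynetError):
    """Invalid or inconsistent input data (negative areas, bad volumes, ...)."""


class StageError(OxynetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
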