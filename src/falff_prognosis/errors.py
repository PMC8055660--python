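"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An input or configuration value makes the requested operation impossible."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. every scan failed quality control)."""
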