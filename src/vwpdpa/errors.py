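"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid domain input (bad durations, malformed trials, ...)."""


class ConfigError(ValueError):
    """Invalid run configuration (unknown fields, overlapping rules, ...)."""


class EstimationError(RuntimeError):
    """A divergence-point estimate could not be produced (e.g. zero
    convergent bootstrap resamples, or an empty group)."""
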