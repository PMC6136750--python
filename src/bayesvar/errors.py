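"""Exception hierarchy shared across the package."""


class BayesvarError(Exception):
    """Base class for all package errors."""


class ConfigError(BayesvarError):
    """Invalid or inconsistent configuration (unknown predictor, bad level code, ...)."""


class InvalidInputError(BayesvarError, ValueError):
    """Malformed input data (all-zero submitter counts, bad counts, ...)."""


class InsufficientTrainingDataError(BayesvarError):
    """Training minima could not be met even after data expansion."""


class SamplerError(BayesvarError):
    """MCMC produced non-finite output or was given a degenerate response."""
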