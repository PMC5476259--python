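"""Exception types shared across pipeline stages."""


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient (e.g. a constant or duplicated predictor)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit or test."""


class DegenerateFitError(ValueError):
    """A quantity is undefined for this fit (e.g. AIC of a saturated model)."""
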