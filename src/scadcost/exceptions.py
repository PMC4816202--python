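"""Exception hierarchy for scadcost."""


class ScadCostError(Exception):
    """Base class for all scadcost errors."""


class ConfigurationError(ScadCostError, ValueError):
    """A simulation or model configuration is invalid; names the offending field."""


class ParameterError(ScadCostError, ValueError):
    """Fitted or supplied parameters imply an impossible quantity (e.g. a negative mean cost)."""


class DataIntegrityError(ScadCostError, ValueError):
    """Input tables are mutually inconsistent (unknown ids, duplicate rows, ...)."""


class SingularDesignError(ScadCostError, RuntimeError):
    """A design matrix is rank deficient; carries the aliased column names."""


class ConvergenceError(ScadCostError, RuntimeError):
    """An iterative fit failed to converge; carries iteration diagnostics."""
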