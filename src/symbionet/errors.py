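"""Exception hierarchy shared across the package.

``ValidationError`` marks malformed or inconsistent inputs (CLI exit code 2);
``InfeasibleModelError`` marks hypotheses that cannot generate the data at
all, e.g. a species with zero spatial overlap everywhere (CLI exit code 3).
"""


class SymbionetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SymbionetError, ValueError):
    """Input data violate a documented contract (bad file, bad labels, bad counts)."""


class InfeasibleModelError(SymbionetError, RuntimeError):
    """A probability model or randomization cannot produce a feasible outcome."""
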