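"""Exception hierarchy for bindkit.

All package-specific failures derive from :class:`BindkitError` so callers can
catch one base class at pipeline level while tests assert on specific leaves.
"""


class BindkitError(Exception):
    """Base class for all bindkit errors."""


class ValidationError(BindkitError, ValueError):
    """Malformed input table or out-of-domain value (names the offending column)."""


class PreconditionError(BindkitError, ValueError):
    """An operation's stated precondition is violated (e.g. too few points)."""


class FitDegenerateError(BindkitError, RuntimeError):
    """A regression produced a physically meaningless result (e.g. intercept <= 0)."""


class IndeterminateIC50Error(BindkitError, RuntimeError):
    """Dose-response data never cross 50% inhibition; IC50 is undefined."""


class NoInhibitionError(BindkitError, RuntimeError):
    """Secondary plot slope <= 0: apparent Km does not rise with [I], Ki undefined."""
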