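"""Exception hierarchy for atommap."""


class AtommapError(Exception):
    """Base class for all package errors."""


class ParseError(AtommapError):
    """Input text could not be parsed into a reaction or molecule."""


class InputError(AtommapError):
    """Structurally valid input that violates a precondition (e.g. empty side)."""


class ChemistryError(AtommapError):
    """Chemically inconsistent structure (unresolvable valence, bad edit)."""


class OutputError(AtommapError):
    """Requested output cannot be produced (e.g. incomplete mapping in strict mode)."""


class BudgetExceeded(AtommapError):
    """Internal signal: the search decision tree outgrew its vertex budget."""
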