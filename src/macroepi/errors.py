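"""Exception hierarchy shared across the package."""


class MacroepiError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MacroepiError, ValueError):
    """A quantity is outside its mathematical domain (e.g. non-positive fitness)."""


class InputError(MacroepiError, ValueError):
    """Malformed or inconsistent user input (files, configs, empty collections)."""


class ModelError(MacroepiError, ValueError):
    """An epistasis model produced an invalid quantity (e.g. mutation rate > 1)."""


class StateError(MacroepiError, RuntimeError):
    """A population or genotype state violates its invariants."""


class InsufficientDataError(MacroepiError, ValueError):
    """Too few eligible points to fit a regression."""
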