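"""Exception hierarchy shared by all pipeline stages."""


class SpanetError(Exception):
    """Base class for all package errors."""


class FormatError(SpanetError):
    """A file does not conform to the expected dialect (bad column, aspect code...)."""


class EmptyInteractomeError(SpanetError):
    """An interactome with no edges was read or asked to be written."""


class ParameterError(SpanetError):
    """An argument is outside its admissible range."""


class MissingProteinError(SpanetError):
    """A referenced protein is absent from the graph or annotation table."""


class PathExplosionError(SpanetError):
    """Exact path enumeration exceeded its cap.

    Carries the partial count so callers can report how far enumeration got.
    """

    def __init__(self, cap: int, partial_count: int):
        self.cap = cap
        self.partial_count = partial_count
        super().__init__(
            f"path enumeration exceeded cap={cap} (partial count {partial_count}); "
            "raise the cap or shorten the path length"
        )


class RandomizationError(SpanetError):
    """Degree-preserving rewiring could not produce an acceptable null network."""
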