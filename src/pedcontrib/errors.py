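"""Exception types raised by pedcontrib."""


class PedigreeError(ValueError):
    """Invalid pedigree structure or content."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"pedigree contains a cycle: {' -> '.join(map(str, self.cycle))}")


class UnknownAnimalError(PedigreeError, KeyError):
    """An animal id does not resolve to a pedigree record."""


class DegenerateTestError(ValueError):
    """A paired test whose differences have zero variance; untestable."""


class FixtureError(RuntimeError):
    """Packaged fixture data is missing or corrupted."""
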