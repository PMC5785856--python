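"""Exception hierarchy.

Every error raised by the public API derives from :class:`PpscanError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class PpscanError(Exception):
    """Base class for all errors raised by ppscan."""


class NewickParseError(PpscanError):
    """Malformed newick input; message names the offending position."""


class SpeciesDecodeError(PpscanError):
    """One or more leaf names could not be resolved to a species code."""

    def __init__(self, leaves):
        self.leaves = list(leaves)
        super().__init__(
            "could not decode species for leaves: " + ", ".join(self.leaves)
        )


class UnknownSpeciesError(PpscanError):
    """Species codes absent from the reference species tree."""

    def __init__(self, species):
        self.species = sorted(species)
        super().__init__(
            "species not present in the species tree: " + ", ".join(self.species)
        )


class UnrootedTreeError(PpscanError):
    """Operation requires a rooted gene tree (root with exactly two children)."""


class NoFocalDuplicationError(PpscanError):
    """No duplication node qualifies for the requested classification."""


class AmbiguousRetentionError(PpscanError):
    """Retention pattern cannot be assigned to T1/T2/T3 unambiguously."""


class ConfigError(PpscanError):
    """Invalid run configuration (unknown keys, out-of-range thresholds)."""
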