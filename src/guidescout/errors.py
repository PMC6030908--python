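"""Exception hierarchy shared across the package."""


class GuidescoutError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GuidescoutError):
    """A file does not conform to its declared format (FASTA, BED, table)."""


class SequenceInputError(GuidescoutError):
    """The pasted/loaded target sequence is unusable (bad characters, too short)."""


class ConfigurationError(GuidescoutError):
    """A score table, profile or enzyme table is malformed or incomplete."""


class UsageError(GuidescoutError):
    """An operation was called with arguments outside its contract."""


class FixtureError(GuidescoutError):
    """The synthetic-genome generator could not satisfy its planting plan."""


class PrimerDesignError(GuidescoutError):
    """No primer pair satisfies the active constraint set; message names the
    binding constraint."""


class ValidationError(GuidescoutError):
    """An output failed its pre-write consistency check (e.g. a CRISPResso row
    whose guide is not contained in its amplicon)."""
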