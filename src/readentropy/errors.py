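"""Exception hierarchy.

All domain errors derive from ValueError so that callers who do not care
about the distinction can catch a single base class.
"""


class ReadEntropyError(ValueError):
    """Base class for all readentropy domain errors."""


class FastaFormatError(ReadEntropyError):
    """Input is not parseable FASTA, or contains an empty record."""


class AlphabetError(ReadEntropyError):
    """A character outside the IUPAC nucleotide alphabet was encountered."""


class DegenerateInputError(ReadEntropyError):
    """No valid substring windows exist (input too short or all-ambiguous)."""


class ConsistencyError(ReadEntropyError):
    """Internal contract violation, e.g. H > H_max or mismatched partition totals."""
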