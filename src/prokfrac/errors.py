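"""Exception hierarchy shared across the package."""


class ProkfracError(Exception):
    """Base class for all errors raised by this package."""


class TaxonomyParseError(ProkfracError, ValueError):
    """A taxonomy string violated the rank-prefix grammar."""


class ProfileFormatError(ProkfracError, ValueError):
    """A condensed-profile file was malformed."""


class TableFormatError(ProkfracError, ValueError):
    """A genome-metadata or taxon-length file was malformed."""


class TaxonNotFoundError(ProkfracError, KeyError):
    """A profile taxon has no entry in the taxon-length table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class SequenceFileError(ProkfracError, ValueError):
    """A read file could not be parsed as FASTA/FASTQ."""
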