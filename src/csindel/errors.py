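"""Exception hierarchy for the pipeline.

Every error raised by the library derives from :class:`CsindelError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class CsindelError(Exception):
    """Base class for all pipeline errors."""


class InputError(CsindelError):
    """Malformed or empty input file."""


class AlignmentShapeError(InputError):
    """Sequences in an alignment do not all share the same length."""


class CharacterError(InputError):
    """A sequence contains a character outside the amino-acid alphabet."""


class PartitionError(CsindelError):
    """In-group/out-group partition is inconsistent with the alignment."""


class ParameterError(CsindelError):
    """A parameter value is outside its documented range."""


class LookupError_(CsindelError):
    """A requested record id is absent from the collection."""


class ComparabilityError(CsindelError):
    """Two gene records cannot be compared (different contigs/genomes)."""


class ConfigError(CsindelError):
    """A synthetic-data configuration describes an impossible geometry."""
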