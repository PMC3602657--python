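"""Exception hierarchy for the dbpred pipeline."""


class DbpredError(Exception):
    """Base class for all dbpred errors."""


class ParseError(DbpredError):
    """A file could not be parsed (malformed FASTA, PSSM, .ss2, ...)."""


class ValidationError(DbpredError):
    """A record or value violates an invariant (bad alphabet, length, range)."""


class ProfileMismatchError(DbpredError):
    """A per-residue profile is inconsistent with its protein sequence."""


class ConfigError(DbpredError):
    """An invalid configuration value."""


class DescriptorUndefinedError(DbpredError):
    """A descriptor is undefined for this input (e.g. sequence too short)."""


class SchemaError(DbpredError):
    """Feature-name / column schema mismatch between fit and apply time."""
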