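"""Exception hierarchy shared across patgen modules."""


class PatgenError(Exception):
    """Base class for all patgen errors."""


# -- structure handling -------------------------------------------------------

class InvalidSmiles(PatgenError):
    """The string could not be interpreted as a molecule."""


class StandardizationFailure(PatgenError):
    """No organic parent structure remained after desalting/normalization."""


class KeyGenerationFailure(PatgenError):
    """The InChIKey layer could not produce an identifier."""


class DescriptorFailure(PatgenError):
    """A molecular descriptor could not be computed; the message names it."""


class UnsupportedKind(PatgenError):
    """Unknown fingerprint kind."""


class KindMismatch(PatgenError):
    """Tanimoto requested between fingerprints of different kinds."""


# -- database / matchers ------------------------------------------------------

class DbNotBuilt(PatgenError):
    """Operation requires a built drug-patent database."""


class IngestionError(PatgenError):
    """A malformed input row was encountered during database build."""


class EmptyReferenceSet(PatgenError):
    """A matcher was given no reference molecules."""


class IndexNotBuilt(PatgenError):
    """LSH queries require a built index."""


# -- corpus / language model --------------------------------------------------

class EmptySource(PatgenError):
    """Curation source contained no records."""


class ConfigError(PatgenError):
    """Invalid configuration values."""


class CorpusTooSmall(PatgenError):
    """Training corpus below the minimum sequence count."""


class NonFiniteLoss(PatgenError):
    """Training loss became NaN/Inf; aborted with diagnostics."""


class UntokenizableCharacter(PatgenError):
    """SMILES contains a character outside the token vocabulary."""


class PrefixTooLong(PatgenError):
    """Prefix length reached the model's maximum sequence length."""


# -- generator / analysis -----------------------------------------------------

class NoExpandableChild(PatgenError):
    """UCT selection called on a node with no children and no untried tokens."""


class EmptyLog(PatgenError):
    """Metrics requested on an empty generation log."""


class TooFewMolecules(PatgenError):
    """Chemical-space embedding needs a minimum combined set size."""


class InvalidQuery(PatgenError):
    """Analog search received an unparseable query structure."""


class SpaceTooSmall(PatgenError):
    """Fixture enumeration space smaller than the requested universe."""


class SampleTooLarge(PatgenError):
    """Requested sample exceeds the available population."""
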