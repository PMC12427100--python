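"""Exception hierarchy shared by all pipeline stages."""


class LipidprogError(Exception):
    """Base class for all package errors."""


# --- nomenclature ---------------------------------------------------------

class UnknownClassError(LipidprogError):
    """Lipid class token (or requested class name) not in the controlled vocabulary."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"unknown lipid class in name: {name!r}")


class MalformedNameError(LipidprogError):
    """Carbon:double-bond tokens of a lipid shorthand name could not be read."""

    def __init__(self, name: str, reason: str = ""):
        self.name = name
        msg = f"malformed lipid name: {name!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


# --- preprocess -----------------------------------------------------------

class EmptyMatrixError(LipidprogError):
    """No species survive a filtering step."""


class AllMissingSpeciesError(LipidprogError):
    """A species has no observed value, so half-minimum imputation is undefined."""


class NonPositiveValueError(LipidprogError):
    """log10 requested on a matrix containing zeros or negative values."""


class PipelineStateError(LipidprogError):
    """Operation applied to a matrix in the wrong state (scale / missingness)."""


# --- diffexp --------------------------------------------------------------

class DegenerateGroupError(LipidprogError):
    """A t-test group has fewer than two values."""


class GroupCountError(LipidprogError):
    """Differential expression requires exactly two group labels."""


class ValueRangeError(LipidprogError):
    """A p-value outside [0, 1]."""


# --- subtype --------------------------------------------------------------

class TooFewSamplesError(LipidprogError):
    """Fewer than five samples: a 2-D embedding is meaningless."""


class DegenerateInputError(LipidprogError):
    """All points identical: K-means has no 2-partition."""


# --- survival -------------------------------------------------------------

class ConstantFeatureError(LipidprogError):
    """All values identical; median stratification impossible."""


class NoEventsError(LipidprogError):
    """No death events at all; log-rank/Cox undefined."""


class NoSharedSamplesError(LipidprogError):
    """Sample-id intersection between two inputs is empty."""


# --- transomics -----------------------------------------------------------

class ConstantVectorError(LipidprogError):
    """Spearman correlation undefined for a constant vector."""


# --- io / config ----------------------------------------------------------

class ParseError(LipidprogError):
    """Malformed input table."""


class DuplicateIdError(LipidprogError):
    """Duplicate species or sample identifiers in an input table."""


class ConfigError(LipidprogError):
    """Invalid configuration value."""
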