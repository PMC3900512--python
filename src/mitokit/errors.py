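"""Exception hierarchy for mitokit."""


class MitokitError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MitokitError, ValueError):
    """Feature coordinates fall outside the genome or are malformed."""


class OrderingError(MitokitError, ValueError):
    """Annotation features are not in the required table order."""


class StateError(MitokitError, ValueError):
    """An operation needs data (e.g. a sequence) that is not present."""


class EmptyInputError(MitokitError, ValueError):
    """An operation received an empty sequence or table."""


class FrameError(MitokitError, ValueError):
    """A coding sequence length is not compatible with codon structure."""


class SpecError(MitokitError, ValueError):
    """A synthetic-genome or evolution spec is infeasible or inconsistent."""


class ParameterError(MitokitError, ValueError):
    """A numeric parameter is out of its legal range."""


class DistanceMatrixError(MitokitError, ValueError):
    """A distance matrix fails validation (asymmetry, negative entries,
    or an undefined pairwise distance)."""


class NewickError(MitokitError, ValueError):
    """Malformed newick text."""
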