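"""Exception hierarchy for the pipeline."""


class ConnclusterError(Exception):
    """Base class for all package errors."""


class DimensionError(ConnclusterError):
    """A matrix is not square, or is empty."""


class StackError(ConnclusterError):
    """Matrices in a stack disagree in dimension or subject count."""


class TableError(ConnclusterError):
    """A phenotype table is malformed (duplicate IDs, non-numeric column)."""


class UndefinedCorrelationError(ConnclusterError):
    """A correlation is undefined because one input vector is constant."""


class ContractError(ConnclusterError):
    """An argument violates a documented precondition (shape, symmetry)."""
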