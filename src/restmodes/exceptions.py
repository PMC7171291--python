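"""Package-wide exception types."""


class InvalidParameterError(ValueError):
    """A parameter violates an operation's contract."""


class RankDeficientError(ValueError):
    """A design or feature matrix is rank deficient.

    Carries ``columns``: indices (or names) of the offending columns.
    """

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConsensusError(RuntimeError):
    """Consensus re-clustering failed to converge.

    Carries ``agreement``: the last agreement matrix, for inspection.
    """

    def __init__(self, message: str, agreement=None):
        super().__init__(message)
        self.agreement = agreement


class DegenerateDataError(ValueError):
    """Input data carry no usable variance.

    ``columns`` lists the offending columns when applicable.
    """

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []
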