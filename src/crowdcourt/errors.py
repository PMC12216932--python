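"""Exception types shared across the package."""


class CrowdCourtError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CrowdCourtError, ValueError):
    """A numeric or structural parameter violates its contract."""


class InvalidInputError(CrowdCourtError, ValueError):
    """Input data (features, labels, files) violates its contract."""


class DegenerateDataError(InvalidInputError):
    """A dataset is missing a class or is otherwise unusable for training."""


class SeatingInfeasibleError(CrowdCourtError, ValueError):
    """A hearing requests more judges than a roster can seat."""


class SchemaError(CrowdCourtError, ValueError):
    """An experiment configuration fails validation.

    ``problems`` lists one human-readable message per offending key.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
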