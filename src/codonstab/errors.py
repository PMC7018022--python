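"""Exception hierarchy for codonstab."""


class CodonstabError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CodonstabError, ValueError):
    """Malformed or out-of-contract input (bad sequence, negative count...)."""


class UndefinedProfileError(CodonstabError, ValueError):
    """A frequency profile cannot be formed (no countable codons/residues)."""


class DegenerateInputError(CodonstabError, ValueError):
    """Input is structurally valid but carries no usable signal (all zeros)."""


class UnreachableTargetError(CodonstabError, ValueError):
    """Requested codon optimality lies outside the protein's feasible range."""

    def __init__(self, target: float, minimum: float, maximum: float):
        self.target, self.minimum, self.maximum = target, minimum, maximum
        super().__init__(
            f"target {target:.1f}% optimal is outside the feasible range "
            f"[{minimum:.1f}%, {maximum:.1f}%] for this protein"
        )


class RankDeficiencyError(CodonstabError, ValueError):
    """Design matrix for a linear model is rank deficient."""


class InsufficientDataError(CodonstabError, ValueError):
    """Too few observations to fit or test."""


class FeasibilityError(CodonstabError, ValueError):
    """No nonnegative anticodon abundance reproduces the requested tAI vector."""
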