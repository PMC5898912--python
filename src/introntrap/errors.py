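"""Exception hierarchy with stable CLI exit codes.

Exit-code contract: 0 success, 2 ineligible input, 3 infeasible design
constraints, 1 internal/other error.
"""


class DesignError(Exception):
    """Base class for all toolkit errors."""
    exit_code = 1


class AnnotationError(DesignError):
    """Malformed or referentially inconsistent genome/annotation input."""


class MalformedModelError(DesignError):
    """Gene/transcript model violates a structural invariant."""


class IneligibleGeneError(DesignError):
    """Target gene fails the coding-intron eligibility filter."""
    exit_code = 2


class InfeasibleConstraintError(DesignError):
    """No design satisfies the stated constraints (arms, enzymes, primers...)."""
    exit_code = 3


class AssemblyError(DesignError):
    """Golden Gate ligation graph has no, or more than one, circular product."""
    exit_code = 3
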