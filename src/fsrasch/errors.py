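"""Exception hierarchy.

User-input problems (bad levels, malformed tables) and numerical problems
(non-convergence, inestimable items) are kept distinct so the command-line
layer can map them to different exit codes.
"""


class FsraschError(Exception):
    """Base class for all package errors."""


class UserInputError(FsraschError):
    """Malformed or inconsistent user input (exit code 1 at the CLI)."""


class CodingError(UserInputError):
    """A raw survey level could not be coded; names the row/item involved."""


class NumericalError(FsraschError):
    """Numerical failure during estimation (exit code 2 at the CLI)."""


class InestimableItemError(NumericalError):
    """Items answered all-affirmative or all-negative carry no finite CML estimate."""

    def __init__(self, item_ids, message=None):
        self.item_ids = list(item_ids)
        super().__init__(
            message or f"items with extreme totals are not estimable: {self.item_ids}"
        )


class ConvergenceError(NumericalError):
    """The Newton iteration did not reach the gradient tolerance."""

    def __init__(self, grad_norm, n_iter, message=None):
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        super().__init__(
            message
            or f"no convergence after {n_iter} iterations (gradient norm {grad_norm:.3e})"
        )


class ExtremeScoreError(FsraschError):
    """A raw score of 0 or k has no finite maximum-likelihood ability estimate."""
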