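"""Exception hierarchy.

``PwmcleaveError`` is the common base so callers (and the CLI) can separate
input problems (:class:`InputError` subtypes, exit code 2) from computation
problems (exit code 3).
"""


class PwmcleaveError(Exception):
    """Base class for all package errors."""


class InputError(PwmcleaveError, ValueError):
    """Malformed or missing user input (files, records, parameters)."""


class SubstrateParseError(InputError):
    """A cleavage-annotated peptide line could not be parsed."""


class MatrixFormatError(InputError):
    """A PWM matrix file violates the on-disk dialect."""


class BackgroundCoverageError(InputError):
    """The background set does not cover the full 20-residue alphabet."""


class UnscorableWindowError(PwmcleaveError):
    """A P3–P2′ window contains a residue with no PWM column value.

    Deliberately distinct from a low score: the window is not comparable
    to the threshold at all.
    """


class DegenerateMatrixError(PwmcleaveError):
    """The PWM has score_min == score_max, so scores carry no information."""
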