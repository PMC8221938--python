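"""Exception hierarchy for refocal.

All refocal errors derive from :class:`RefocalError` so callers can catch
the package's failures with a single except clause; the CLI maps them to
exit code 2.
"""


class RefocalError(Exception):
    """Base class for all refocal errors."""


class ValidationError(RefocalError):
    """An input value is non-finite or violates a type invariant."""


class SingularDriveError(RefocalError):
    """The drive places the focus at the conjugate-plane singularity.

    Raised when ``|kappa * Z_ERROR + 1|`` falls below tolerance: the remote
    focus unit output is then imaged to infinity and no finite focus exists.
    """


class SingularTargetError(RefocalError):
    """The requested target lies at the conjugate-plane singularity.

    Raised when ``|z_corr * Z_ERROR + n f^2|`` (mm^2) falls below tolerance.
    """


class NoFocusError(RefocalError):
    """The traced ray fan is collimated in image space; no finite focus."""


class PlacementError(RefocalError):
    """Bead placement with the requested minimum separation failed."""


class DegenerateDesignError(RefocalError):
    """The calibration design cannot constrain the misalignment parameters
    (e.g. a single z plane, all curvatures equal, or no trajectories)."""


class NonConvergenceError(RefocalError):
    """The nonlinear refinement failed to converge within the iteration cap."""


class AmbiguityWarning(UserWarning):
    """Two linking candidates tie within tolerance; the tie was broken by
    smaller distance, then lower detection index."""
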