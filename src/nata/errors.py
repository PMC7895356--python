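"""Exception hierarchy for non-adherence tree analysis."""


class NataError(Exception):
    """Base class for all package-specific errors."""


class TreeValidationError(NataError, ValueError):
    """A node violates the tree schema (bad kind/gate/rate combination)."""


class TreeStructureError(NataError, ValueError):
    """The node graph is not a tree (cycle, orphan, duplicate or missing id)."""


class MissingFactorError(NataError, KeyError):
    """A factor was requested from a study that never observed it.

    Not observing a factor is distinct from observing zero occurrences.
    """


class CapabilityError(NataError, ValueError):
    """The requested computation is outside this engine's supported model class."""


class DegenerateRatesError(NataError, ValueError):
    """Coincident partial rate sums make the sequential-gate closed form singular.

    Perturb one of the rates by a tiny amount to break the tie.
    """
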