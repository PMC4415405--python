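"""Exception hierarchy for colonydiff."""


class ColonyDiffError(Exception):
    """Base class for all colonydiff errors."""


class ConfigurationError(ColonyDiffError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class GeometryError(ColonyDiffError, ValueError):
    """A geometric constraint is violated (colony outside domain, line
    outside frame, imaging window outside the solved domain, ...)."""


class ColonyNotFoundError(ColonyDiffError, RuntimeError):
    """No colony-sized object could be segmented in the stain channel."""


class InsufficientDataError(ColonyDiffError, ValueError):
    """Too few usable data points remain for a fit."""


class UnknownScenarioError(ColonyDiffError, KeyError):
    """Requested fixture scenario is not one of the documented presets."""
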