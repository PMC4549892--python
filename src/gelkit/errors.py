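"""Exception hierarchy for gelkit.

Everything user-facing derives from :class:`GelKitError` so callers can catch
one base class; subclasses mirror the failure domains of the pipeline
(format, geometry, marker matching, model fitting, comparability, storage).
"""


class GelKitError(Exception):
    """Base class for all gelkit errors."""


class FormatError(GelKitError):
    """Unsupported or unreadable image/file format."""


class DomainError(GelKitError, ValueError):
    """Parameter or geometry outside its valid domain."""


class InsufficientMarkerError(GelKitError):
    """Too few detected positions to match a reference marker (need >= 3)."""


class FitError(GelKitError):
    """No migration model could be fitted (non-convergent or non-monotone)."""


class ExtrapolationError(GelKitError):
    """Row lies beyond the fitted migration-model domain plus its 10% margin."""


class NormalizationError(GelKitError):
    """Shift-field construction failed (e.g. no reference lane)."""


class ComparabilityError(GelKitError):
    """Two lanes cannot be compared (different reference markers, no overlap)."""


class StoreError(GelKitError):
    """Study/experiment persistence failure (corrupt file, version mismatch)."""


class IncompleteBundleError(StoreError):
    """An experiment bundle is missing a required part (e.g. its marker)."""
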