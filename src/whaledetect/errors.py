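"""Exception hierarchy for the whaledetect pipeline.

Every stage raises a subclass of :class:`WhaleDetectError` so orchestration can
abort with a stage-tagged diagnostic instead of a bare traceback.
"""


class WhaleDetectError(Exception):
    """Base class for all whaledetect errors."""


class ParameterError(WhaleDetectError, ValueError):
    """An invalid parameter value (non-positive GSD, bad threshold, ...)."""


class SceneGeometryError(WhaleDetectError, ValueError):
    """A target cannot be placed inside the scene (e.g. whale longer than the
    scene extent)."""


class GridError(WhaleDetectError, ValueError):
    """Tile-grid construction or application failed (scene smaller than one
    tile, inconsistent pan/MS grids, ...)."""


class ConfigurationError(WhaleDetectError, ValueError):
    """A run configuration is inconsistent (missing band, unknown model, ...)."""


class UnsupportedArchitectureError(ConfigurationError):
    """The requested backbone is not available in this build."""


class PretrainedWeightsUnavailableError(ConfigurationError):
    """pretrained=True was requested but no pretrained weights exist for the
    backbone."""


class DegenerateInputError(WhaleDetectError, ValueError):
    """An input is degenerate for the requested operation (zero-variance
    simulated pan, empty instance mask, single-class training set, ...)."""


class TrainingDivergedError(WhaleDetectError, RuntimeError):
    """A non-finite loss was encountered during optimisation."""
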