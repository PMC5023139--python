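"""Exception hierarchy shared across the package."""


class FluxForestError(Exception):
    """Base class for all package errors."""


class NetworkError(FluxForestError):
    """Malformed or inconsistent metabolic network definition."""


class TracerError(FluxForestError):
    """Invalid substrate labeling specification."""


class MeasurementError(FluxForestError):
    """Invalid measurement specification or missing fragment."""


class RatioError(FluxForestError):
    """Invalid or undefined flux-ratio evaluation."""


class InfeasibleError(FluxForestError):
    """Constraint set admits no feasible flux vector."""


class SamplingError(FluxForestError):
    """Flux sampling failed to produce the requested cohort."""


class SimulationError(FluxForestError):
    """Isotope-labeling simulation failure (singular balance, bad pool)."""


class PredictorError(FluxForestError):
    """Predictor training/prediction contract violation."""
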