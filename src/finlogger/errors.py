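"""Exception types shared across the pipeline stages."""


class FinloggerError(Exception):
    """Base class for all package-specific errors."""


class GenerationError(FinloggerError):
    """A synthetic-data generator could not honour its contract
    (e.g. the fish silhouette would be clipped by the frame border)."""


class NoFishDetected(FinloggerError):
    """No contour passed the area and length/width filters."""


class AmbiguousDetection(FinloggerError):
    """More than one contour passed the selection filters."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            f"{len(self.candidates)} objects passed the selection filters: "
            + ", ".join(
                f"(area={a:.0f} px^2, ratio={r:.2f})" for a, r in self.candidates
            )
        )


class NoMinimum(FinloggerError):
    """The fitted cost-of-transport curve has no interior minimum
    (non-convex quadratic)."""


class ConfigError(FinloggerError):
    """A run configuration file contains an unknown key or a value of
    the wrong type."""


class ChannelMissing(FinloggerError):
    """A required biologger channel is absent from the input."""
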