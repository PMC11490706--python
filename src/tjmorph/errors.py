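"""Exception hierarchy for tjmorph."""


class TJMorphError(Exception):
    """Base class for all tjmorph errors."""


class DegenerateEdge(TJMorphError):
    """Edge endpoints coincide; no chord exists to ruffle."""


class DegenerateHistogram(TJMorphError):
    """Histogram has fewer than two occupied bins; no threshold is defined."""


class NotASkeleton(TJMorphError):
    """Input mask is not 1-px thin outside junction-node clusters."""


class LoopBranch(TJMorphError):
    """Zigzag index requested for a loop (chord length zero)."""


class EmptyBand(TJMorphError):
    """Intensity requested over an empty band mask."""


class UndefinedCorrelation(TJMorphError):
    """Pearson correlation undefined (zero variance or < 2 samples)."""


class PipelineError(TJMorphError):
    """A pipeline stage failed; message carries the stage label."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")
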