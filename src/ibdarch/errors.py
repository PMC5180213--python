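"""Named exceptions raised across the pipeline."""


class IbdArchError(Exception):
    """Base class for all package errors."""


class UnknownSiteError(IbdArchError):
    """An effect or selection references a site absent from the panel."""


class UnknownSampleError(IbdArchError):
    """A pool references a sample absent from the genotype matrix."""


class EmptyStratumError(IbdArchError):
    """Pools were requested for a stratum with no samples."""


class TooFewPoolsError(IbdArchError):
    """Fewer than two pools per arm: between-pool variance is inestimable."""


class UnsortedInputError(IbdArchError):
    """Sites must be sorted by (chromosome, position)."""


class EmptyGeneSetError(IbdArchError):
    """A gene set references no simulated/annotated genes."""


class MismatchedRecordsError(IbdArchError):
    """Screen and validation records refer to different sites or comparisons."""


class ConfigError(IbdArchError):
    """A run configuration failed validation."""
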