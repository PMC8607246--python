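"""Exception hierarchy shared across the pipeline stages."""


class SomaticFunnelError(Exception):
    """Base class for all package errors."""


class VcfFormatError(SomaticFunnelError):
    """The VCF file is structurally invalid (e.g. missing #CHROM header)."""


class RecordError(SomaticFunnelError):
    """A single VCF record could not be parsed or is inconsistent."""


class ReferenceMismatchError(SomaticFunnelError):
    """A variant's REF allele disagrees with the reference sequence."""


class BoundaryError(SomaticFunnelError):
    """Left normalization would require bases before position 1."""


class NormalizationError(SomaticFunnelError):
    """A variant that must be left-normalized is not."""


class ConfigurationError(SomaticFunnelError):
    """Missing resource, unknown database name, or invalid run configuration."""


class StageError(SomaticFunnelError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ProfileError(SomaticFunnelError):
    """A synthetic cohort profile violates its internal count identities."""
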