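"""Exception types shared across the pipeline stages."""


class MamutspecError(Exception):
    """Base class for all package-specific errors."""


class DuplicateContigError(MamutspecError):
    """A FASTA file declares the same contig name twice."""


class UnknownContigError(MamutspecError, KeyError):
    """A lookup referenced a contig not present in the index/genome."""


class UnsupportedVariantError(MamutspecError, ValueError):
    """Allele pair outside the supported SNV/INS/DEL classes (e.g. MNP, symbolic)."""


class MalformedGenotypeError(MamutspecError, ValueError):
    """A VCF GT field could not be interpreted as a diploid genotype."""


class DegenerateInputError(MamutspecError, ValueError):
    """Statistical input with no usable variation (e.g. all groups constant)."""


class ConfigError(MamutspecError, ValueError):
    """Invalid simulation or filter configuration."""
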