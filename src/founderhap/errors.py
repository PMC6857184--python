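"""Exception hierarchy shared across the package.

The CLI maps these onto its exit codes; library users catch them directly.
"""


class FounderhapError(Exception):
    """Base class for all package errors."""


class FileFormatError(FounderhapError):
    """A panel/PED/genotype/popmap/VCF input violates its format contract."""


class PanelMismatchError(FounderhapError):
    """Two objects that must share a marker panel do not."""


class MendelianError(FounderhapError):
    """Family genotypes admit no zero-recombination Mendelian phasing."""


class NoCarrierError(FounderhapError):
    """No sample carries the requested mutant allele."""


class LDError(FounderhapError):
    """LD computation is undefined for the given input (monomorphic/missing)."""


class EnumerationCapError(FounderhapError):
    """Exact phase enumeration would exceed the configured configuration cap."""
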