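"""Exception hierarchy. Every module raises a subclass of SdrcovError so the
command-line layer can report a one-line cause and exit nonzero."""


class SdrcovError(Exception):
    """Base class for all package errors."""


class AlignmentError(SdrcovError):
    """Malformed multiple sequence alignment (ragged rows, bad characters)."""


class ProfileError(SdrcovError):
    """Malformed PWM input (negative entries, bad sums, missing ids)."""


class WeightsError(SdrcovError):
    """Invalid sequence-weight input."""


class TreeError(SdrcovError):
    """Guide-tree / alignment mismatch or unusable tree."""


class MappingError(SdrcovError):
    """Site-map entry that cannot be resolved against the structure."""


class GapError(SdrcovError):
    """A gapped alignment column reached a gap-free computation; the site
    filter should have removed it."""


class ParameterError(SdrcovError):
    """Out-of-range numeric parameter (e.g. log base <= 1)."""


class GeneratorSpecError(SdrcovError):
    """Impossible synthetic-data specification."""


class InsufficientDataError(SdrcovError):
    """Too few rows / pairs for the requested computation."""
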