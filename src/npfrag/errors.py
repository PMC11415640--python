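"""Exception types shared across the package."""


class NpfragError(Exception):
    """Base class for package errors."""


class ParseError(NpfragError, ValueError):
    """A SMILES string or input record could not be parsed."""


class UnsupportedElementError(NpfragError, ValueError):
    """Structure contains an element outside the supported C,H,N,O,P,S set."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(f"unsupported element: {element!r} (supported: C,H,N,O,P,S)")


class InfeasibleLossError(NpfragError, ValueError):
    """Composition subtraction would produce a negative element count."""


class ConfigurationError(NpfragError, ValueError):
    """Invalid parameter value (unknown adduct, non-positive tolerance, ...)."""


class DegenerateSpectrumError(NpfragError, ValueError):
    """Spectrum has no usable peaks (e.g. all intensities zero)."""


class RuleDefinitionError(NpfragError, ValueError):
    """A cleavage-reconstruction rule violates atom conservation."""
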