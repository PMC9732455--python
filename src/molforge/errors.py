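"""Exception types shared across the package."""


class MolforgeError(Exception):
    """Base class for all package errors."""


class InvalidSmilesError(MolforgeError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"invalid SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ConfigurationError(MolforgeError, ValueError):
    """An invalid option, unknown enum member, or uncompilable pattern."""


class SimilarityUndefinedError(MolforgeError, ZeroDivisionError):
    """A similarity measure is undefined for the given pair (e.g. McConnaughey
    on an all-zero fingerprint)."""


class EmptyNetworkError(MolforgeError, ValueError):
    """No valid rows survived interaction-network construction, or an
    operation was applied to an empty network."""


class VocabularyError(MolforgeError, KeyError):
    """A token outside the generator vocabulary was encountered at encode time."""


class DegeneratePanelError(MolforgeError, ValueError):
    """A docking-score panel cannot be min-max rescaled (fewer than two
    distinct values)."""


class NoOverlapError(MolforgeError, RuntimeError):
    """Forward/backward energy-difference distributions do not overlap enough
    to bracket the BAR self-consistency root; add more lambda windows."""
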