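"""Exception hierarchy for latticedesign."""


class LatticeDesignError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LatticeDesignError, ValueError):
    """Invalid input: bad sequence, malformed conformation, inconsistent config."""


class EnsembleTooLargeError(LatticeDesignError):
    """Requested exhaustive conformation ensemble exceeds the enumeration cap."""


class FeasibilityError(LatticeDesignError):
    """Exhaustive sequence-space work exceeds the enumeration cap."""


class InfiniteFreeEnergyGapError(LatticeDesignError):
    """Folding probability is exactly 0 or 1, so the two-state gap diverges."""
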