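"""Exception hierarchy for the cas9rvl pipeline."""


class ValidationError(ValueError):
    """Invalid user-supplied value (wrong length, alphabet, range...)."""


class UnassignableRead(ValueError):
    """A read that cannot be classified against the target layout.

    Raised by :func:`cas9rvl.library.classify_species`; counting code catches
    it and tallies the read as unassigned rather than aborting.
    """


class ConfigurationError(ValueError):
    """Incomplete or inconsistent configuration (e.g. missing penalty entry)."""


class NormalizationError(ValueError):
    """A reference population is empty or has zero counts in a needed sample."""


class AnalysisError(RuntimeError):
    """A precondition of an analysis step is violated (e.g. WT not cleaved)."""
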