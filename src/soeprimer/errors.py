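"""Exception hierarchy for soeprimer."""


class SoePrimerError(Exception):
    """Base class for all soeprimer errors."""


class SequenceError(SoePrimerError):
    """Invalid nucleotide sequence or FASTA input."""


class ConfigError(SoePrimerError):
    """Invalid design/thermo configuration."""


class ThermoError(SoePrimerError):
    """Melting-temperature computation cannot proceed."""


class DesignError(SoePrimerError):
    """Primer enumeration is impossible for the given fragments/config."""


class AmplificationError(SoePrimerError):
    """A simulated PCR reaction fails (no/ambiguous priming, no product)."""
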