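"""Exception hierarchy shared across the simulator."""


class FedcepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FedcepError):
    """A spec/config object violates its invariants."""


class DataError(FedcepError):
    """Input data violates a precondition (missing column, shape mismatch...)."""


class ArgumentError(FedcepError):
    """A scalar argument is out of its admissible range."""


class NumericError(FedcepError):
    """A numeric routine failed to reach its tolerance."""


class SecurityError(FedcepError):
    """A cryptographic precondition was violated (e.g. nonce reuse)."""


class KeyError_(FedcepError):
    """Unknown key id presented for decryption."""


class LedgerError(FedcepError):
    """Ledger serialization or persistence failure."""
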