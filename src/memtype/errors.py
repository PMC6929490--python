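"""Package-specific exception types."""


class TrainingDiverged(RuntimeError):
    """Raised when a training loss becomes non-finite."""


class ModelPersistenceError(RuntimeError):
    """Raised when a saved model cannot be restored (corrupt or wrong version)."""
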